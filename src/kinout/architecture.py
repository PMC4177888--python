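"""Domain-architecture construction and hybrid/rogue classification.

The architecture of a kinase is the ordered list of its assigned domains.
Comparing it against the canonical-architecture registry yields one of four
verdicts:

* ``canonical`` — the architecture matches a template of the kinase's own
  subfamily;
* ``hybrid_single_domain`` — it instead matches a template of another
  subfamily and consists of the kinase catalytic domain alone;
* ``hybrid_multi_domain`` — it matches another subfamily's template and
  carries non-kinase domains;
* ``rogue`` — it matches no known subfamily's template at all.

Two auxiliary reports flag features the registry cannot express: terminal
overhangs (>= 100 residues N- or C-terminal of the first/last assigned
domain) and Asn/Gln-rich low-complexity insertions inside the kinase domain,
a hallmark of Plasmodium falciparum kinases.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .io import DomainHit
from .registry import ArchitectureTemplate, CanonicalRegistry

__all__ = [
    "DomainArchitecture",
    "ArchitectureCall",
    "InsertReport",
    "resolve_overlaps",
    "build_architecture",
    "collapse_architecture",
    "architecture_string",
    "match_architecture",
    "classify_kinase",
    "detect_overhangs",
    "detect_low_complexity_inserts",
    "flag_orphans",
]

LABELS = ("canonical", "hybrid_single_domain", "hybrid_multi_domain", "rogue")


@dataclass(frozen=True)
class DomainArchitecture:
    """Ordered, non-overlapping assigned domains on one sequence."""

    seq_id: str
    ordered_domains: tuple[tuple[str, int, int], ...]
    seq_len: int

    def __post_init__(self) -> None:
        prev_end = 0
        for name, lo, hi in self.ordered_domains:
            if not 0 <= lo < hi <= self.seq_len:
                raise ValueError(f"{self.seq_id}: domain {name} interval [{lo},{hi}) "
                                 f"outside sequence of length {self.seq_len}")
            if lo < prev_end:
                raise ValueError(f"{self.seq_id}: overlapping domain intervals")
            prev_end = hi

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(name for name, _, _ in self.ordered_domains)


@dataclass
class InsertReport:
    """An Asn/Gln-rich low-complexity stretch inside the kinase domain."""

    seq_id: str
    ins_from: int
    ins_to: int
    nq_fraction: float


@dataclass
class ArchitectureCall:
    """Per-kinase verdict with overhang/insert side reports."""

    seq_id: str
    assigned_subfamily: str
    architecture: DomainArchitecture
    label: str
    source_subfamilies: tuple[str, ...] = ()
    orphan: bool = False
    n_overhang: int = 0
    c_overhang: int = 0
    overhang_flagged: bool = False
    inserts: list[InsertReport] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")
        if self.label in ("canonical", "rogue") and self.source_subfamilies:
            raise ValueError(f"{self.label} call cannot carry source subfamilies")
        if self.label.startswith("hybrid") and not self.source_subfamilies:
            raise ValueError("hybrid call must carry at least one source subfamily")


def resolve_overlaps(hits: Sequence[DomainHit], max_overlap: int = 10) -> list[DomainHit]:
    """Resolve conflicting domain assignments on one sequence.

    When two domains are assigned to the same region, the one with the
    longer span and better e-value wins.  Greedy: rank hits by span length
    (descending), then e-value (ascending), then start position; accept a
    hit only if it overlaps every already-accepted hit by at most
    ``max_overlap`` residues.  Nested hits always conflict.  Output is
    sorted by start position and independent of input order.
    """
    ranked = sorted(hits, key=lambda h: (-h.span, h.evalue, h.seq_from, h.domain))
    accepted: list[DomainHit] = []
    for hit in ranked:
        ok = True
        for kept in accepted:
            overlap = min(hit.seq_to, kept.seq_to) - max(hit.seq_from, kept.seq_from)
            if overlap > max_overlap:
                ok = False
                break
        if ok:
            accepted.append(hit)
    return sorted(accepted, key=lambda h: h.seq_from)


def build_architecture(resolved_hits: Sequence[DomainHit], seq_len: int,
                       seq_id: str | None = None) -> DomainArchitecture:
    """Assemble the ordered architecture from non-overlapping hits.

    Overlapping input (beyond touching at a shared boundary) violates the
    contract and raises; an empty hit list yields a zero-domain architecture.
    Hits whose intervals overlap by a tolerated margin (see
    :func:`resolve_overlaps`) are trimmed at the midpoint of the overlap so
    the stored intervals are strictly disjoint.
    """
    hits = sorted(resolved_hits, key=lambda h: h.seq_from)
    if seq_id is None:
        seq_id = hits[0].seq_id if hits else ""
    domains: list[tuple[str, int, int]] = []
    for h in hits:
        lo, hi = h.seq_from, h.seq_to
        if domains and lo < domains[-1][2]:
            overlap = domains[-1][2] - lo
            if overlap > 10:
                raise ValueError(f"{seq_id}: hits overlap by {overlap} residues; "
                                 "run resolve_overlaps first")
            mid = lo + overlap // 2
            prev = domains[-1]
            domains[-1] = (prev[0], prev[1], mid)
            lo = mid
        domains.append((h.domain, lo, hi))
    return DomainArchitecture(seq_id=seq_id, ordered_domains=tuple(domains), seq_len=seq_len)


def collapse_architecture(arch: DomainArchitecture) -> list[tuple[str, int]]:
    """Collapse maximal runs of identical adjacent domain names into
    (name, count) pairs."""
    runs: list[tuple[str, int]] = []
    for name in arch.names:
        if runs and runs[-1][0] == name:
            runs[-1] = (name, runs[-1][1] + 1)
        else:
            runs.append((name, 1))
    return runs


def architecture_string(arch: DomainArchitecture) -> str:
    """Canonical collapsed text form, e.g. ``"C1+C2+Pkinase"`` or
    ``"Pkinase+EF-hand{3}"``."""
    parts = []
    for name, count in collapse_architecture(arch):
        parts.append(name if count == 1 else f"{name}{{{count}}}")
    return "+".join(parts) if parts else "(none)"


def match_architecture(arch: DomainArchitecture, template: ArchitectureTemplate) -> bool:
    """True iff the collapsed architecture aligns token-by-token with the
    template, each run count inside the token's repeat range."""
    runs = collapse_architecture(arch)
    if len(runs) != len(template.tokens):
        return False
    for (name, count), (t_name, lo, hi) in zip(runs, template.tokens):
        if name != t_name or not lo <= count <= hi:
            return False
    return True


def classify_kinase(
    assignment,
    arch: DomainArchitecture,
    registry: CanonicalRegistry,
) -> ArchitectureCall:
    """Compare an architecture against the canonical registry and emit the
    hybrid/rogue verdict.

    ``assignment`` is the sequence's :class:`~kinout.annotation.SubfamilyAssignment`
    (only ``seq_id`` and ``subfamily`` are used).  The assigned subfamily
    must exist in the registry.
    """
    subfamily = assignment.subfamily
    if subfamily not in registry:
        raise KeyError(f"unknown subfamily {subfamily!r}")
    if any(match_architecture(arch, t) for t in registry.templates(subfamily)):
        return ArchitectureCall(
            seq_id=assignment.seq_id,
            assigned_subfamily=subfamily,
            architecture=arch,
            label="canonical",
        )
    sources = sorted(
        other
        for other, templates in registry.subfamilies.items()
        if other != subfamily and any(match_architecture(arch, t) for t in templates)
    )
    if sources:
        names = arch.names
        single = len(names) == 1 and names[0] in registry.kinase_domain_names
        label = "hybrid_single_domain" if single else "hybrid_multi_domain"
        return ArchitectureCall(
            seq_id=assignment.seq_id,
            assigned_subfamily=subfamily,
            architecture=arch,
            label=label,
            source_subfamilies=tuple(sources),
        )
    return ArchitectureCall(
        seq_id=assignment.seq_id,
        assigned_subfamily=subfamily,
        architecture=arch,
        label="rogue",
    )


def detect_overhangs(
    arch: DomainArchitecture, seq_len: int | None = None, min_overhang: int = 100
) -> tuple[int, int, bool]:
    """Measure the residues N-terminal of the first assigned domain and
    C-terminal of the last; flag when either reaches ``min_overhang``."""
    if not arch.ordered_domains:
        raise ValueError(f"{arch.seq_id}: cannot measure overhangs of an empty architecture")
    if seq_len is None:
        seq_len = arch.seq_len
    n_overhang = arch.ordered_domains[0][1]
    c_overhang = seq_len - arch.ordered_domains[-1][2]
    return n_overhang, c_overhang, (n_overhang >= min_overhang or c_overhang >= min_overhang)


def detect_low_complexity_inserts(
    seq: str,
    kinase_span: tuple[int, int],
    window: int = 50,
    nq_threshold: float = 0.4,
    seq_id: str = "",
) -> list[InsertReport]:
    """Find Asn/Gln-rich low-complexity insertions inside the kinase span.

    A sliding window of ``window`` residues moves across the span; windows
    whose N+Q fraction reaches ``nq_threshold`` are merged into maximal
    runs.  Each run is reported as one insert covering the union of its
    qualifying windows, with ``nq_fraction`` the mean fraction over those
    windows (hence always >= the threshold).  Spans shorter than the window
    yield no reports.
    """
    lo, hi = kinase_span
    if not 0 <= lo < hi <= len(seq):
        raise ValueError(f"kinase span {kinase_span} outside sequence of length {len(seq)}")
    span = seq[lo:hi]
    if len(span) < window:
        return []
    is_nq = [1 if c in "NQ" else 0 for c in span]
    # rolling N+Q count
    running = sum(is_nq[:window])
    fractions: list[float] = [running / window]
    for i in range(1, len(span) - window + 1):
        running += is_nq[i + window - 1] - is_nq[i - 1]
        fractions.append(running / window)
    reports: list[InsertReport] = []
    run_start: int | None = None
    run_fracs: list[float] = []

    def _close(end_index: int) -> None:
        nonlocal run_start, run_fracs
        if run_start is None:
            return
        reports.append(
            InsertReport(
                seq_id=seq_id,
                ins_from=lo + run_start,
                ins_to=lo + end_index - 1 + window,
                nq_fraction=sum(run_fracs) / len(run_fracs),
            )
        )
        run_start, run_fracs = None, []

    for i, frac in enumerate(fractions):
        if frac >= nq_threshold:
            if run_start is None:
                run_start = i
            run_fracs.append(frac)
        else:
            _close(i)
    _close(len(fractions))
    return reports


def flag_orphans(calls: Iterable[ArchitectureCall]) -> list[ArchitectureCall]:
    """Mark non-canonical calls whose collapsed architecture occurs exactly
    once in the dataset as orphans; canonical calls are never orphans."""
    calls = list(calls)
    counts = Counter(architecture_string(c.architecture) for c in calls)
    for call in calls:
        call.orphan = (
            call.label != "canonical"
            and counts[architecture_string(call.architecture)] == 1
        )
    return calls
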