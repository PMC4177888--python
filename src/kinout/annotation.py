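"""Kinase-candidate filtering, subfamily assignment and catalytic-motif checks.

A sequence enters the kinase dataset when a subfamily-profile hit survives
three filters (sequence length > 200 residues, per-domain e-value <= 1e-4,
profile coverage >= 70%), is assigned to the best subfamily whose profile it
matches with >= 30% sequence identity, and is kept as a putative active
kinase only if the catalytic-loop aspartate is found: the consensus is
HRDLKxxN, with the catalytic Asp at the third position and a conserved Asn
five residues downstream (as in PKA's HRDLKPEN).  Substitutions at the
H/R/L/K positions are tolerated — such kinases are likely still functional —
so they are scored but never grounds for exclusion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .io import DomainHit, SequenceRecord

__all__ = [
    "SubfamilyAssignment",
    "MotifHit",
    "filter_kinase_candidates",
    "assign_subfamily",
    "choose_assignment",
    "profile_identity",
    "locate_catalytic_motif",
    "is_putative_active",
]

#: consensus residues at window offsets 0,1,3,4 (D at 2 and N at 7 are mandatory)
_CONSENSUS_OPTIONAL = {0: "H", 1: "R", 3: "L", 4: "K"}
MOTIF_WINDOW = 8


@dataclass(frozen=True)
class SubfamilyAssignment:
    """A sequence assigned to a kinase subfamily by profile identity."""

    seq_id: str
    subfamily: str
    identity: float
    kinase_span: tuple[int, int]
    coverage: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError(f"{self.seq_id}: identity {self.identity} outside [0, 1]")
        if not 0.0 <= self.coverage <= 1.0:
            raise ValueError(f"{self.seq_id}: coverage {self.coverage} outside [0, 1]")
        lo, hi = self.kinase_span
        if not 0 <= lo < hi:
            raise ValueError(f"{self.seq_id}: bad kinase span {self.kinase_span}")


@dataclass(frozen=True)
class MotifHit:
    """Located catalytic-loop motif: Asp position, paired Asn, context."""

    d_position: int
    n_position: int
    window: str
    consensus_matches: int

    def __post_init__(self) -> None:
        if self.n_position != self.d_position + 5:
            raise ValueError("catalytic Asn must sit five residues after the Asp")
        if not 2 <= self.consensus_matches <= 6:
            raise ValueError("consensus_matches must be in 2..6")


def _seq_index(seqs: Iterable[SequenceRecord] | Mapping[str, SequenceRecord]) -> Mapping[str, SequenceRecord]:
    if isinstance(seqs, Mapping):
        return seqs
    return {rec.id: rec for rec in seqs}


def filter_kinase_candidates(
    hits: Sequence[DomainHit],
    seqs: Iterable[SequenceRecord] | Mapping[str, SequenceRecord],
    min_len: int = 200,
    max_evalue: float = 1e-4,
    min_coverage: float = 0.70,
) -> list[DomainHit]:
    """Apply the kinase-candidate filters to subfamily-profile hits.

    Retains exactly the hits whose sequence is longer than ``min_len``
    residues, whose per-domain e-value is at most ``max_evalue`` and whose
    profile coverage ``(hmm_to - hmm_from) / profile_len`` is at least
    ``min_coverage``.  A hit naming an unknown sequence id is an error.
    """
    index = _seq_index(seqs)
    kept: list[DomainHit] = []
    for hit in hits:
        if hit.seq_id not in index:
            raise KeyError(f"hit references unknown sequence id {hit.seq_id!r}")
        if len(index[hit.seq_id]) <= min_len:
            continue
        if hit.evalue > max_evalue:
            continue
        if hit.coverage < min_coverage:
            continue
        kept.append(hit)
    return kept


def assign_subfamily(
    candidate: DomainHit,
    alignment_identity: float,
    min_identity: float = 0.30,
) -> SubfamilyAssignment | None:
    """Assign the candidate hit's subfamily if identity meets the threshold.

    ``alignment_identity`` is the fraction of identical residue pairs over
    aligned columns of the hit.  The 30% boundary is inclusive.  Returns
    ``None`` (unassigned) below threshold.
    """
    if not 0.0 <= alignment_identity <= 1.0:
        raise ValueError(f"identity {alignment_identity} outside [0, 1]")
    if alignment_identity < min_identity:
        return None
    return SubfamilyAssignment(
        seq_id=candidate.seq_id,
        subfamily=candidate.domain,
        identity=alignment_identity,
        kinase_span=(candidate.seq_from, candidate.seq_to),
        coverage=min(candidate.coverage, 1.0),
    )


def choose_assignment(assignments: Iterable[SubfamilyAssignment]) -> SubfamilyAssignment | None:
    """Pick the winning assignment when several profiles pass the threshold:
    highest identity wins, ties broken alphabetically by subfamily name."""
    candidates = list(assignments)
    if not candidates:
        return None
    return min(candidates, key=lambda a: (-a.identity, a.subfamily))


def profile_identity(seq: str, hit: DomainHit, profile_consensus: str) -> float:
    """Ungapped identity between the hit's aligned sequence stretch and the
    matching stretch of the profile consensus (compared position-by-position
    over the shorter of the two stretches)."""
    sub_seq = seq[hit.ali_from : hit.ali_to]
    sub_prof = profile_consensus[hit.hmm_from : hit.hmm_to]
    n = min(len(sub_seq), len(sub_prof))
    if n == 0:
        return 0.0
    same = sum(1 for a, b in zip(sub_seq[:n], sub_prof[:n]) if a == b)
    return same / n


def locate_catalytic_motif(seq: str, kinase_span: tuple[int, int]) -> MotifHit | None:
    """Scan the kinase span for the HRDLKxxN catalytic-loop motif.

    Every 8-residue window inside the span qualifies when position 2 is D
    and position 7 is N.  Among qualifying windows the one with the most
    consensus matches wins (H/R/L/K at positions 0/1/3/4, plus the two
    mandatory residues; maximum 6); ties go to the leftmost window.
    Returns ``None`` when no window qualifies — the sequence is then not a
    putative active kinase.
    """
    lo, hi = kinase_span
    if not 0 <= lo < hi <= len(seq):
        raise ValueError(f"kinase span {kinase_span} outside sequence of length {len(seq)}")
    best: MotifHit | None = None
    for start in range(lo, hi - MOTIF_WINDOW + 1):
        window = seq[start : start + MOTIF_WINDOW]
        if window[2] != "D" or window[7] != "N":
            continue
        matches = 2 + sum(
            1 for pos, res in _CONSENSUS_OPTIONAL.items() if window[pos] == res
        )
        if best is None or matches > best.consensus_matches:
            best = MotifHit(
                d_position=start + 2,
                n_position=start + 7,
                window=window,
                consensus_matches=matches,
            )
    return best


def is_putative_active(motif: MotifHit | None) -> bool:
    """A sequence is a putative active kinase iff the catalytic Asp was found."""
    return motif is not None
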