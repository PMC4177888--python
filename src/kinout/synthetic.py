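"""Seeded synthetic-kinome generator.

Emulates a kinome drawn from K subfamilies.  Each subfamily owns a distinct
random kinase-core consensus of ~250 residues carrying the HRDLKPEN
catalytic motif at a fixed internal offset, plus a canonical non-kinase
domain complement drawn from an "inner pool" of domain families; an "outer
pool" of domain families never appears in any canonical template and is
reserved for rogue events.  Per-sequence events are planted at configurable
rates:

* hybrid — the sequence keeps its own kinase core but adopts the complete
  canonical complement of a different (donor) subfamily; a single-domain
  hybrid arises when the donor's canonical form is the bare kinase domain;
* rogue — an outer-pool domain is spliced into the sequence's own canonical
  complement, yielding an architecture canonical for no subfamily;
* overhang — >= 100 unassigned residues are prepended or appended;
* low-complexity insert (plasmodium mode) — a poly-Asn/Gln stretch is
  inserted inside the kinase domain.

The generator emits FASTA-ready sequences, a simulated hmmscan-style hit
table whose coordinates are exact by construction (e-values sampled well
inside the pipeline's thresholds, coverage >= 0.9), and a truth table
recording every planted event.  One random stream per sequence, derived
from (seed, index), keeps outputs byte-identical under a fixed seed and
stable when single sequences are added or removed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .io import DomainHit, SequenceRecord, write_domtblout, write_fasta
from .registry import ArchitectureTemplate, CanonicalRegistry, save_canonical_registry

__all__ = [
    "KinomeConfig",
    "TruthRecord",
    "DomainLibrary",
    "Kinome",
    "make_toy_registry",
    "generate_kinome",
    "write_synthetic_outputs",
    "read_truth_table",
]

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
MOTIF = "HRDLKPEN"
KINASE_DOMAIN = "Pkinase"

INNER_POOL = ("SH2", "SH3", "C1", "C2", "PH", "PDZ", "EF-hand", "Ig", "SAM",
              "FN3", "ANK", "WD40", "TM", "CNH", "PB1", "UBA")
OUTER_POOL = ("MORN", "PAS", "L27", "DUF3354", "ATG16", "DAXX", "Filament", "KELCH")

LABEL_CANONICAL = "canonical"
LABEL_HYBRID_SINGLE = "hybrid_single_domain"
LABEL_HYBRID_MULTI = "hybrid_multi_domain"
LABEL_ROGUE = "rogue"


@dataclass(frozen=True)
class KinomeConfig:
    """Study conditions for one synthetic kinome."""

    n_sequences: int = 200
    n_subfamilies: int = 10
    kinase_core_length: int = 250
    mutation_rate: float = 0.05
    hybrid_rate: float = 0.0
    rogue_rate: float = 0.0
    overhang_rate: float = 0.0
    insert_rate: float = 0.0
    plasmodium_mode: bool = False
    ablate_motif: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        rates = (self.mutation_rate, self.hybrid_rate, self.rogue_rate,
                 self.overhang_rate, self.insert_rate)
        if any(not 0 <= r <= 1 for r in rates):
            raise ValueError("rates must lie in [0, 1]")
        if self.hybrid_rate + self.rogue_rate > 1:
            raise ValueError("hybrid_rate + rogue_rate must not exceed 1")
        if self.n_subfamilies < 2:
            raise ValueError("need at least two subfamilies")


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one generated sequence."""

    seq_id: str
    subfamily: str
    true_label: str
    source_subfamily: str | None
    overhang_planted: bool
    insert_planted: bool


@dataclass
class DomainLibrary:
    """Concrete sequences for every domain family and subfamily core."""

    domain_seqs: dict[str, str]
    subfamily_cores: dict[str, str]
    core_motif_offset: int
    inner_pool: tuple[str, ...]
    outer_pool: tuple[str, ...]


@dataclass
class Kinome:
    records: list[SequenceRecord]
    hits: list[DomainHit]
    truth: list[TruthRecord]
    registry: CanonicalRegistry
    library: DomainLibrary


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(AMINO_ACIDS[rng.integers(0, len(AMINO_ACIDS), size=length)])


def make_toy_registry(
    n_subfamilies: int,
    seed: int,
    kinase_core_length: int = 250,
) -> tuple[CanonicalRegistry, DomainLibrary]:
    """Build a registry of ``n_subfamilies`` subfamilies with a domain library.

    Guarantees: subfamily SF01 is a bare single-kinase-domain subfamily and
    SF02 carries a repeat-range complement (EF-hand{2,4}); every kinase core
    contains exactly one HRDLKPEN motif at a fixed internal offset; inner
    and outer domain pools are disjoint and the outer pool appears in no
    template.  Deterministic for a fixed seed.
    """
    if n_subfamilies < 2:
        raise ValueError("need at least two subfamilies")
    rng = np.random.default_rng([seed, 104729])
    domain_seqs: dict[str, str] = {}
    for name in INNER_POOL + OUTER_POOL:
        length = int(rng.integers(50, 81))
        domain_seqs[name] = _random_protein(rng, length)

    offset = kinase_core_length // 2
    sf_names = [f"SF{i + 1:02d}" for i in range(n_subfamilies)]
    cores: dict[str, str] = {}
    for name in sf_names:
        while True:
            core = _random_protein(rng, kinase_core_length)
            core = core[:offset] + MOTIF + core[offset + len(MOTIF):]
            if core.count(MOTIF) == 1:
                break
        cores[name] = core

    templates: dict[str, frozenset[ArchitectureTemplate]] = {}
    seen_shapes: set[tuple[str, ...]] = set()
    pool = [d for d in INNER_POOL if d != "EF-hand"]
    for i, name in enumerate(sf_names):
        if i == 0:
            tokens = ((KINASE_DOMAIN, 1, 1),)
        elif i == 1:
            tokens = ((KINASE_DOMAIN, 1, 1), ("EF-hand", 2, 4))
        else:
            while True:
                k = int(rng.integers(1, 4))
                picks = [str(x) for x in rng.choice(pool, size=k, replace=False)]
                slot = int(rng.integers(0, k + 1))
                names = tuple(picks[:slot] + [KINASE_DOMAIN] + picks[slot:])
                if names not in seen_shapes and names != (KINASE_DOMAIN,):
                    break
            tokens = tuple((n, 1, 1) for n in names)
        seen_shapes.add(tuple(t[0] for t in tokens))
        templates[name] = frozenset({ArchitectureTemplate(tokens)})

    registry = CanonicalRegistry(templates, frozenset({KINASE_DOMAIN}))
    library = DomainLibrary(
        domain_seqs=domain_seqs,
        subfamily_cores=cores,
        core_motif_offset=offset,
        inner_pool=INNER_POOL,
        outer_pool=OUTER_POOL,
    )
    return registry, library


def _mutate_core(rng: np.random.Generator, core: str, rate: float,
                 motif_offset: int) -> str:
    """Point-mutate the core at ``rate``, sparing the motif window."""
    residues = list(core)
    protected = set(range(motif_offset, motif_offset + len(MOTIF)))
    mask = rng.random(len(residues)) < rate
    for i in np.nonzero(mask)[0]:
        if int(i) in protected:
            continue
        current = residues[i]
        choices = [a for a in AMINO_ACIDS if a != current]
        residues[i] = choices[int(rng.integers(0, len(choices)))]
    return "".join(residues)


def _instantiate_template(
    rng: np.random.Generator, template: ArchitectureTemplate
) -> list[str]:
    """Expand a template into a concrete ordered domain-name list, choosing
    each repeat count uniformly inside its range."""
    out: list[str] = []
    for name, lo, hi in template.tokens:
        count = int(rng.integers(lo, hi + 1))
        out.extend([name] * count)
    return out


def generate_kinome(
    registry: CanonicalRegistry,
    library: DomainLibrary,
    config: KinomeConfig,
) -> Kinome:
    """Generate sequences, a simulated hit table and the truth table."""
    sf_names = sorted(registry.subfamilies)
    records: list[SequenceRecord] = []
    hits: list[DomainHit] = []
    truth: list[TruthRecord] = []
    offset = library.core_motif_offset

    for idx in range(config.n_sequences):
        rng = np.random.default_rng([config.seed, 7919, idx])
        seq_id = f"syn{idx + 1:05d}"
        subfamily = sf_names[int(rng.integers(0, len(sf_names)))]

        u = rng.random()
        if u < config.hybrid_rate:
            event = "hybrid"
        elif u < config.hybrid_rate + config.rogue_rate:
            event = "rogue"
        else:
            event = "canonical"
        overhang = rng.random() < config.overhang_rate
        insert = config.plasmodium_mode and rng.random() < config.insert_rate

        consensus = library.subfamily_cores[subfamily]
        core_len = len(consensus)
        core = _mutate_core(rng, consensus, config.mutation_rate, offset)
        if config.ablate_motif:
            # knock out the catalytic Asp (D -> E) for negative controls
            core = core[: offset + 2] + "E" + core[offset + 3:]

        source: str | None = None
        if event == "hybrid":
            donors = [s for s in sf_names if s != subfamily]
            source = donors[int(rng.integers(0, len(donors)))]
            template = sorted(registry.templates(source), key=str)[0]
        else:
            template = sorted(registry.templates(subfamily), key=str)[0]
        domain_names = _instantiate_template(rng, template)

        if event == "rogue":
            extra = library.outer_pool[int(rng.integers(0, len(library.outer_pool)))]
            pos = int(rng.integers(0, len(domain_names) + 1))
            domain_names.insert(pos, extra)

        insert_len = 0
        if insert:
            insert_len = int(rng.integers(60, 91))
            n_or_q = np.where(rng.random(insert_len) < 0.8, "N", "Q")
            stretch = "".join(n_or_q)
            # splice in downstream of the motif, away from the domain ends
            at = int(rng.integers(offset + len(MOTIF) + 20, core_len - 20))
            core = core[:at] + stretch + core[at:]

        parts: list[str] = []
        intervals: list[tuple[str, int, int]] = []
        cursor = 0

        def _append(fragment: str, name: str | None) -> None:
            nonlocal cursor
            if name is not None:
                intervals.append((name, cursor, cursor + len(fragment)))
            parts.append(fragment)
            cursor += len(fragment)

        lead = _random_protein(rng, int(rng.integers(0, 31)))
        if overhang and rng.random() < 0.5:
            lead = _random_protein(rng, int(rng.integers(100, 181)))
        _append(lead, None)
        for k, name in enumerate(domain_names):
            if k > 0:
                _append(_random_protein(rng, int(rng.integers(5, 26))), None)
            fragment = core if name == KINASE_DOMAIN else library.domain_seqs[name]
            _append(fragment, name)
        tail = _random_protein(rng, int(rng.integers(0, 31)))
        if overhang and len(lead) < 100:
            tail = _random_protein(rng, int(rng.integers(100, 181)))
        _append(tail, None)

        seq = "".join(parts)
        records.append(SequenceRecord(id=seq_id, seq=seq, organism="synthetic"))

        for name, lo, hi in intervals:
            profile_len = core_len if name == KINASE_DOMAIN else len(library.domain_seqs[name])
            hits.append(
                DomainHit(
                    seq_id=seq_id, domain=name,
                    seq_from=lo, seq_to=hi,
                    hmm_from=0, hmm_to=profile_len, profile_len=profile_len,
                    evalue=float(10.0 ** -rng.uniform(8, 40)),
                )
            )
            if name == KINASE_DOMAIN:
                # the subfamily-profile hit used for assignment
                hits.append(
                    DomainHit(
                        seq_id=seq_id, domain=subfamily,
                        seq_from=lo, seq_to=hi,
                        hmm_from=0, hmm_to=core_len, profile_len=core_len,
                        evalue=float(10.0 ** -rng.uniform(8, 40)),
                    )
                )

        if event == "hybrid":
            donor_is_single = domain_names == [KINASE_DOMAIN]
            label = LABEL_HYBRID_SINGLE if donor_is_single else LABEL_HYBRID_MULTI
        elif event == "rogue":
            label = LABEL_ROGUE
        else:
            label = LABEL_CANONICAL
        truth.append(
            TruthRecord(
                seq_id=seq_id, subfamily=subfamily, true_label=label,
                source_subfamily=source,
                overhang_planted=overhang, insert_planted=insert,
            )
        )

    return Kinome(records=records, hits=hits, truth=truth,
                  registry=registry, library=library)


def write_synthetic_outputs(kinome: Kinome, directory: str | Path) -> dict[str, Path]:
    """Write sequences.fasta, hits.domtblout, truth.tsv, registry.json and
    profiles.fasta (subfamily core consensi) into ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": directory / "sequences.fasta",
        "hits": directory / "hits.domtblout",
        "truth": directory / "truth.tsv",
        "registry": directory / "registry.json",
        "profiles": directory / "profiles.fasta",
    }
    write_fasta(kinome.records, paths["fasta"])
    write_domtblout(kinome.hits, {r.id: len(r) for r in kinome.records}, paths["hits"])
    with open(paths["truth"], "w") as fh:
        fh.write("seq_id\tsubfamily\ttrue_label\tsource_subfamily\t"
                 "overhang_planted\tinsert_planted\n")
        for t in kinome.truth:
            fh.write(
                f"{t.seq_id}\t{t.subfamily}\t{t.true_label}\t"
                f"{t.source_subfamily or '-'}\t{int(t.overhang_planted)}\t"
                f"{int(t.insert_planted)}\n"
            )
    save_canonical_registry(kinome.registry, paths["registry"])
    write_fasta(
        [SequenceRecord(id=name, seq=core)
         for name, core in sorted(kinome.library.subfamily_cores.items())],
        paths["profiles"],
    )
    return paths


def read_truth_table(path: str | Path) -> list[TruthRecord]:
    records: list[TruthRecord] = []
    lines = Path(path).read_text().splitlines()
    for line in lines[1:]:
        seq_id, subfamily, label, source, over, ins = line.split("\t")
        records.append(
            TruthRecord(
                seq_id=seq_id, subfamily=subfamily, true_label=label,
                source_subfamily=None if source == "-" else source,
                overhang_planted=bool(int(over)), insert_planted=bool(int(ins)),
            )
        )
    return records
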