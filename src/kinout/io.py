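"""Readers and writers for the external formats the pipeline touches.

Sequences travel as FASTA, profile/domain hits as HMMER3 ``domtblout`` tables
or RPS-BLAST-style tabular output.  All coordinates are converted at the
boundary to 0-based half-open intervals; nothing downstream ever sees the
1-based inclusive conventions of the search tools.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SearchIO, SeqIO

__all__ = [
    "SequenceRecord",
    "DomainHit",
    "read_fasta",
    "write_fasta",
    "parse_domain_hits",
    "write_domtblout",
]

_AA = set("ACDEFGHIKLMNPQRSTVWYX")


@dataclass(frozen=True)
class SequenceRecord:
    """One protein sequence: identifier, free organism tag, residues."""

    id: str
    seq: str
    organism: str = ""

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"sequence {self.id!r} is empty")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class DomainHit:
    """One profile hit on a sequence.

    ``seq_from``/``seq_to`` are the envelope coordinates used for domain
    architecture building; ``ali_from``/``ali_to`` are the alignment
    coordinates used for identity computation.  Both are 0-based half-open
    on the sequence.  ``hmm_from``/``hmm_to`` index the profile the same way.
    ``evalue`` is the independent (per-domain) e-value.  ``identity`` is an
    optional pre-computed fractional sequence identity (RPS-BLAST tables
    carry one; domtblout does not).
    """

    seq_id: str
    domain: str
    seq_from: int
    seq_to: int
    hmm_from: int
    hmm_to: int
    profile_len: int
    evalue: float
    ali_from: int = -1
    ali_to: int = -1
    identity: float | None = None

    def __post_init__(self) -> None:
        if self.ali_from < 0:
            object.__setattr__(self, "ali_from", self.seq_from)
            object.__setattr__(self, "ali_to", self.seq_to)
        if not 0 <= self.seq_from < self.seq_to:
            raise ValueError(
                f"{self.seq_id}/{self.domain}: bad sequence interval "
                f"[{self.seq_from}, {self.seq_to})"
            )
        if not 0 <= self.hmm_from < self.hmm_to <= self.profile_len:
            raise ValueError(
                f"{self.seq_id}/{self.domain}: bad profile interval "
                f"[{self.hmm_from}, {self.hmm_to}) for profile_len={self.profile_len}"
            )
        if self.evalue <= 0:
            raise ValueError(f"{self.seq_id}/{self.domain}: e-value must be > 0")

    @property
    def span(self) -> int:
        return self.seq_to - self.seq_from

    @property
    def coverage(self) -> float:
        """Fraction of the profile covered by the hit."""
        return (self.hmm_to - self.hmm_from) / self.profile_len


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a protein FASTA file into :class:`SequenceRecord` objects.

    The header token before the first whitespace becomes the id; an
    ``organism=`` key anywhere in the description becomes the organism tag.
    Sequences are uppercased.  Duplicate ids raise ``ValueError``.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip() == "":
                continue
            if not line.startswith(">"):
                raise ValueError(
                    f"{path}: line {lineno}: expected FASTA header, got {line.strip()!r}"
                )
            break
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        organism = ""
        for token in rec.description.split():
            if token.startswith("organism="):
                organism = token[len("organism="):]
        records.append(SequenceRecord(id=rec.id, seq=str(rec.seq).upper(), organism=organism))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.id}"
            if rec.organism:
                header += f" organism={rec.organism}"
            fh.write(header + "\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def parse_domain_hits(path: str | Path, dialect: str = "domtblout") -> list[DomainHit]:
    """Parse a profile-hit table into :class:`DomainHit` objects.

    ``dialect`` is ``"domtblout"`` (HMMER3 per-domain table as written by
    ``hmmscan --domtblout``) or ``"rpsblast_tab"`` (BLAST outfmt-6-like with
    columns qseqid sseqid pident length qstart qend sstart send evalue slen).
    Coordinates are converted from each dialect's 1-based inclusive
    convention to 0-based half-open; the independent (per-domain) e-value is
    used for domtblout.
    """
    path = Path(path)
    if dialect == "domtblout":
        return _parse_domtblout(path)
    if dialect == "rpsblast_tab":
        return _parse_rpsblast_tab(path)
    raise ValueError(f"unknown hit-table dialect {dialect!r}")


def _parse_domtblout(path: Path) -> list[DomainHit]:
    hits: list[DomainHit] = []
    try:
        for qres in SearchIO.parse(str(path), "hmmscan3-domtab"):
            for hit in qres:
                for hsp in hit:
                    # SearchIO already yields 0-based half-open coordinates
                    # and reports the i-Evalue as hsp.evalue.
                    hits.append(
                        DomainHit(
                            seq_id=qres.id,
                            domain=hit.id,
                            seq_from=hsp.env_start,
                            seq_to=hsp.env_end,
                            ali_from=hsp.query_start,
                            ali_to=hsp.query_end,
                            hmm_from=hsp.hit_start,
                            hmm_to=hsp.hit_end,
                            profile_len=hit.seq_len,
                            evalue=float(hsp.evalue),
                        )
                    )
    except ValueError as exc:
        raise ValueError(f"{path}: malformed domtblout table: {exc}") from exc
    return hits


_RPS_COLUMNS = [
    "qseqid", "sseqid", "pident", "length",
    "qstart", "qend", "sstart", "send", "evalue", "slen",
]


def _parse_rpsblast_tab(path: Path) -> list[DomainHit]:
    try:
        table = pd.read_csv(
            path, sep=r"\s+", comment="#", header=None,
            names=_RPS_COLUMNS, dtype={"qseqid": str, "sseqid": str},
        )
    except pd.errors.EmptyDataError:
        return []
    hits: list[DomainHit] = []
    for row in table.itertuples(index=False):
        try:
            hits.append(
                DomainHit(
                    seq_id=row.qseqid,
                    domain=row.sseqid,
                    seq_from=int(row.qstart) - 1,
                    seq_to=int(row.qend),
                    hmm_from=int(row.sstart) - 1,
                    hmm_to=int(row.send),
                    profile_len=int(row.slen),
                    evalue=float(row.evalue),
                    identity=float(row.pident) / 100.0,
                )
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: malformed RPS-BLAST row {tuple(row)!r}: {exc}") from exc
    return hits


_DOMTBL_HEADER = (
    "#%-22s %-10s %5s %-20s %-10s %5s %9s %6s %5s %3s %3s %9s %9s %6s %5s "
    "%5s %5s %5s %5s %5s %5s %4s %s\n"
) % (
    " target name", "accession", "tlen", "query name", "accession", "qlen",
    "E-value", "score", "bias", "#", "of", "c-Evalue", "i-Evalue", "score",
    "bias", "from", "to", "from", "to", "from", "to", "acc",
    "description of target",
)


def write_domtblout(hits: Sequence[DomainHit], seq_lens: dict[str, int], path: str | Path) -> None:
    """Write hits in HMMER3 ``hmmscan --domtblout`` layout (1-based inclusive).

    Alignment and envelope coordinate pairs are both emitted; score/bias
    columns are placeholders, as only coordinates and e-values are modelled.
    """
    by_query: dict[str, list[DomainHit]] = {}
    for h in hits:
        by_query.setdefault(h.seq_id, []).append(h)
    with open(path, "w") as fh:
        fh.write(_DOMTBL_HEADER)
        for seq_id, group in by_query.items():
            n = len(group)
            for k, h in enumerate(sorted(group, key=lambda x: x.seq_from), start=1):
                fh.write(
                    "%-23s %-10s %5d %-20s %-10s %5d %9.2g %6.1f %5.1f "
                    "%3d %3d %9.2g %9.2g %6.1f %5.1f %5d %5d %5d %5d %5d %5d %4.2f %s\n"
                    % (
                        h.domain, "-", h.profile_len, seq_id, "-",
                        seq_lens[seq_id], h.evalue, 0.0, 0.0, k, n,
                        h.evalue, h.evalue, 0.0, 0.0,
                        h.hmm_from + 1, h.hmm_to,
                        h.ali_from + 1, h.ali_to,
                        h.seq_from + 1, h.seq_to,
                        0.99, "-",
                    )
                )
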