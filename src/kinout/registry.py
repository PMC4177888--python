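"""Canonical domain-architecture registry.

Every kinase subfamily has a characteristic ("canonical") domain
architecture: an ordered list of domain families around exactly one kinase
catalytic domain, possibly with variable repeat counts (e.g. CDPK-type
kinases carry 2 or 4 EF-hand domains).  The registry maps each subfamily to
the set of architecture templates considered canonical for it, and names
which domain families count as the catalytic domain.

Template strings use ``+``-separated tokens with optional repeat ranges:
``Ig{1,5}+TM+Pkinase`` or ``Pkinase+EF-hand{2,4}``; ``{n}`` abbreviates
``{n,n}`` and a bare token means ``{1,1}``.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "ArchitectureTemplate",
    "CanonicalRegistry",
    "parse_template",
    "load_canonical_registry",
    "save_canonical_registry",
]

_TOKEN_RE = re.compile(r"^(?P<name>[^{}+\s]+)(?:\{(?P<lo>\d+)(?:,(?P<hi>\d+))?\})?$")


@dataclass(frozen=True)
class ArchitectureTemplate:
    """Ordered domain tokens with per-token repeat ranges."""

    tokens: tuple[tuple[str, int, int], ...]

    def __post_init__(self) -> None:
        if not self.tokens:
            raise ValueError("architecture template has no tokens")
        for name, lo, hi in self.tokens:
            if lo < 1 or hi < lo:
                raise ValueError(f"bad repeat range {{{lo},{hi}}} for token {name!r}")

    def kinase_tokens(self, kinase_domain_names: Iterable[str]) -> list[str]:
        names = set(kinase_domain_names)
        return [name for name, _, _ in self.tokens if name in names]

    def __str__(self) -> str:
        parts = []
        for name, lo, hi in self.tokens:
            if lo == hi == 1:
                parts.append(name)
            elif lo == hi:
                parts.append(f"{name}{{{lo}}}")
            else:
                parts.append(f"{name}{{{lo},{hi}}}")
        return "+".join(parts)


def parse_template(text: str) -> ArchitectureTemplate:
    """Parse ``"Ig{1,5}+TM+Pkinase"`` into an :class:`ArchitectureTemplate`."""
    tokens: list[tuple[str, int, int]] = []
    for raw in text.strip().split("+"):
        m = _TOKEN_RE.match(raw.strip())
        if m is None:
            raise ValueError(f"unparseable architecture token {raw!r} in {text!r}")
        lo = int(m.group("lo")) if m.group("lo") else 1
        hi = int(m.group("hi")) if m.group("hi") else lo
        tokens.append((m.group("name"), lo, hi))
    return ArchitectureTemplate(tuple(tokens))


@dataclass(frozen=True)
class CanonicalRegistry:
    """Subfamily -> canonical architecture templates, plus the names of the
    domain families treated as the kinase catalytic domain."""

    subfamilies: Mapping[str, frozenset[ArchitectureTemplate]]
    kinase_domain_names: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "subfamilies",
            {k: frozenset(v) for k, v in self.subfamilies.items()},
        )
        object.__setattr__(self, "kinase_domain_names", frozenset(self.kinase_domain_names))
        if not self.kinase_domain_names:
            raise ValueError("registry declares no kinase domain names")
        for subfamily, templates in self.subfamilies.items():
            if not templates:
                raise ValueError(f"subfamily {subfamily!r} has no templates")
            for t in templates:
                n_kinase = len(t.kinase_tokens(self.kinase_domain_names))
                if n_kinase != 1:
                    raise ValueError(
                        f"subfamily {subfamily!r} template {t} has {n_kinase} kinase-domain "
                        "tokens; exactly one is required"
                    )

    def __contains__(self, subfamily: str) -> bool:
        return subfamily in self.subfamilies

    def templates(self, subfamily: str) -> frozenset[ArchitectureTemplate]:
        try:
            return self.subfamilies[subfamily]
        except KeyError:
            raise KeyError(f"unknown subfamily {subfamily!r}") from None


def load_canonical_registry(path: str | Path) -> CanonicalRegistry:
    """Load a registry from JSON or TSV.

    JSON: ``{"kinase_domain_names": [...], "subfamilies": {name: [template, ...]}}``.
    TSV: a ``# kinase_domains: A,B`` header line, then ``subfamily<TAB>template``
    rows (one row per template; subfamilies may repeat).
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = json.loads(path.read_text())
        kinase_names = frozenset(payload["kinase_domain_names"])
        subfamilies = {
            name: frozenset(parse_template(t) for t in templates)
            for name, templates in payload["subfamilies"].items()
        }
        return CanonicalRegistry(subfamilies, kinase_names)
    kinase_names: frozenset[str] = frozenset()
    subfamilies: dict[str, set[ArchitectureTemplate]] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if body.startswith("kinase_domains:"):
                kinase_names = frozenset(
                    x.strip() for x in body[len("kinase_domains:"):].split(",") if x.strip()
                )
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}: line {lineno}: expected 'subfamily<TAB>template'")
        subfamily, template = parts
        subfamilies.setdefault(subfamily.strip(), set()).add(parse_template(template))
    return CanonicalRegistry(
        {k: frozenset(v) for k, v in subfamilies.items()}, kinase_names
    )


def save_canonical_registry(registry: CanonicalRegistry, path: str | Path) -> None:
    """Write a registry as JSON or TSV depending on the file suffix."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = {
            "kinase_domain_names": sorted(registry.kinase_domain_names),
            "subfamilies": {
                name: sorted(str(t) for t in templates)
                for name, templates in sorted(registry.subfamilies.items())
            },
        }
        path.write_text(json.dumps(payload, indent=2) + "\n")
        return
    lines = ["# kinase_domains: " + ",".join(sorted(registry.kinase_domain_names))]
    for name, templates in sorted(registry.subfamilies.items()):
        for t in sorted(str(x) for x in templates):
            lines.append(f"{name}\t{t}")
    path.write_text("\n".join(lines) + "\n")
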