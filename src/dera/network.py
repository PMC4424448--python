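"""Signed prior regulatory networks.

The prior network is a set of directed, signed edges ("regulations"): gene A
activates or inhibits gene B. Networks are read from plain-text edge lists
(SIF-style three-column files or headered TSV) rather than queried from
pathway databases; any curated signed edge list works. Gene identifiers are
opaque, case-sensitive strings — no symbol normalization is attempted.
"""

from __future__ import annotations

import enum
import logging
from collections.abc import Iterable, Iterator
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

logger = logging.getLogger(__name__)

__all__ = [
    "Effect",
    "Regulation",
    "RegulatoryNetwork",
    "NetworkParseError",
    "read_network",
    "write_network",
    "restrict_to_genes",
    "example_network",
]


class NetworkParseError(ValueError):
    """Raised when a network file cannot be parsed."""


class Effect(enum.Enum):
    """Sign of a regulation: transcriptional activation or inhibition."""

    ACTIVATION = "activation"
    INHIBITION = "inhibition"

    def __repr__(self) -> str:  # terser in test diffs
        return f"Effect.{self.name}"


#: Accepted effect tokens (lower-cased) for the SIF3 dialect.
_EFFECT_TOKENS = {
    "activation": Effect.ACTIVATION,
    "activates": Effect.ACTIVATION,
    "->": Effect.ACTIVATION,
    "1": Effect.ACTIVATION,
    "+": Effect.ACTIVATION,
    "inhibition": Effect.INHIBITION,
    "inhibits": Effect.INHIBITION,
    "-|": Effect.INHIBITION,
    "-1": Effect.INHIBITION,
    "-": Effect.INHIBITION,
}


@dataclass(frozen=True)
class Regulation:
    """A signed directed edge of the prior network.

    Identity is the full triple ``(source, target, effect)``: the same gene
    pair with both effects yields two distinct regulations.
    """

    source: str
    target: str
    effect: Effect

    def __post_init__(self) -> None:
        if not self.source or not self.target:
            raise ValueError("regulation endpoints must be non-empty strings")
        if not isinstance(self.effect, Effect):
            raise TypeError(f"effect must be an Effect, got {self.effect!r}")

    @property
    def is_self_loop(self) -> bool:
        return self.source == self.target

    @property
    def sort_key(self) -> tuple[str, str, str]:
        return (self.source, self.target, self.effect.value)

    def __str__(self) -> str:
        arrow = "->" if self.effect is Effect.ACTIVATION else "-|"
        return f"{self.source} {arrow} {self.target}"


@dataclass(frozen=True)
class RegulatoryNetwork:
    """An immutable set of :class:`Regulation` edges.

    ``gene_universe`` is always exactly the set of genes incident to the
    regulations; it is derived, never stored independently.
    """

    regulations: frozenset[Regulation] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "regulations", frozenset(self.regulations))

    @property
    def gene_universe(self) -> frozenset[str]:
        return frozenset(
            g for r in self.regulations for g in (r.source, r.target)
        )

    @property
    def self_loops(self) -> frozenset[Regulation]:
        return frozenset(r for r in self.regulations if r.is_self_loop)

    def contradictory_pairs(self) -> frozenset[tuple[str, str]]:
        """Gene pairs carrying both an activation and an inhibition edge."""
        seen: dict[tuple[str, str], set[Effect]] = {}
        for r in self.regulations:
            seen.setdefault((r.source, r.target), set()).add(r.effect)
        return frozenset(k for k, v in seen.items() if len(v) == 2)

    def sorted_regulations(self) -> list[Regulation]:
        return sorted(self.regulations, key=lambda r: r.sort_key)

    def __len__(self) -> int:
        return len(self.regulations)

    def __iter__(self) -> Iterator[Regulation]:
        return iter(self.regulations)

    def __contains__(self, item: object) -> bool:
        return item in self.regulations


def _parse_effect(token: str, lineno: int) -> Effect:
    try:
        return _EFFECT_TOKENS[token.lower()]
    except KeyError:
        raise NetworkParseError(
            f"line {lineno}: unknown effect token {token!r}"
        ) from None


def read_network(path: str | Path, dialect: str = "sif3") -> RegulatoryNetwork:
    """Read a signed edge list into a :class:`RegulatoryNetwork`.

    Parameters
    ----------
    path
        Edge-list file. ``sif3`` dialect: whitespace- or tab-separated
        ``source effect target`` rows, ``#`` comments allowed. ``tsv_header``
        dialect: tab-separated with a ``source<TAB>effect<TAB>target`` header.
    dialect
        ``"sif3"`` (default) or ``"tsv_header"``.

    Duplicate triples are collapsed (the count is logged and exposed as the
    ``duplicates_collapsed`` attribute of the returned network, alongside
    ``n_contradictory_pairs``). Contradictory pairs — the same gene pair with
    both effects — are retained as two distinct regulations.
    """
    path = Path(path)
    if dialect not in ("sif3", "tsv_header"):
        raise ValueError(f"unknown dialect {dialect!r}")
    lines = path.read_text().splitlines()
    start = 0
    if dialect == "tsv_header":
        if not lines:
            raise NetworkParseError(f"{path}: empty file")
        header = [h.strip().lower() for h in lines[0].split("\t")]
        if header != ["source", "effect", "target"]:
            raise NetworkParseError(
                f"{path}: expected header 'source\\teffect\\ttarget', got {lines[0]!r}"
            )
        start = 1

    regulations: set[Regulation] = set()
    duplicates = 0
    for lineno, raw in enumerate(lines[start:], start=start + 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t") if dialect == "tsv_header" else line.split()
        if len(fields) != 3:
            raise NetworkParseError(
                f"{path}, line {lineno}: expected 3 fields, got {len(fields)}"
            )
        source, effect_token, target = (f.strip() for f in fields)
        reg = Regulation(source, target, _parse_effect(effect_token, lineno))
        if reg in regulations:
            duplicates += 1
        else:
            regulations.add(reg)

    if not regulations:
        raise NetworkParseError(f"{path}: no regulations found (empty network)")

    net = RegulatoryNetwork(frozenset(regulations))
    contradictions = net.contradictory_pairs()
    # read-report attributes; not part of network identity/equality
    object.__setattr__(net, "duplicates_collapsed", duplicates)
    object.__setattr__(net, "n_contradictory_pairs", len(contradictions))
    if duplicates:
        logger.info("%s: collapsed %d duplicate regulation(s)", path, duplicates)
    if contradictions:
        logger.info(
            "%s: %d gene pair(s) carry both effects (kept as distinct regulations)",
            path,
            len(contradictions),
        )
    return net


def write_network(net: RegulatoryNetwork, path: str | Path) -> None:
    """Write a network as canonical SIF3: ``source effect target``, rows
    sorted by (source, target, effect), tokens ``activation``/``inhibition``."""
    path = Path(path)
    with path.open("w") as fh:
        for r in net.sorted_regulations():
            fh.write(f"{r.source}\t{r.effect.value}\t{r.target}\n")


def restrict_to_genes(
    net: RegulatoryNetwork, genes: Iterable[str]
) -> RegulatoryNetwork:
    """Sub-network of regulations with *both* endpoints in ``genes``.

    An empty result is a warning, not an error: downstream operations handle
    empty networks.
    """
    genes = set(genes)
    if not genes:
        raise ValueError("gene set must be non-empty")
    kept = frozenset(
        r for r in net.regulations if r.source in genes and r.target in genes
    )
    dropped = len(net.regulations) - len(kept)
    if dropped:
        logger.info("restrict_to_genes: dropped %d regulation(s)", dropped)
    if not kept:
        logger.warning("restrict_to_genes: no regulations remain")
    return RegulatoryNetwork(kept)


def example_network() -> RegulatoryNetwork:
    """Small bundled breast-cancer-flavoured signed network for demos/tests."""
    ref = resources.files("dera.data").joinpath("example_network.sif")
    with resources.as_file(ref) as p:
        return read_network(p, dialect="sif3")
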