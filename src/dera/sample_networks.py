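"""Sample-specific regulation networks.

Each tumor's column of the ternary indicator matrix is overlaid on the prior
signed network. A regulation (A, B, effect) is kept for that sample only if
both genes are differentially expressed and their signs are consistent with
the effect: activation requires A and B to move in the same direction (both
over- or both under-expressed), inhibition requires opposite directions.

The unit kept — a :class:`RegulationInstance` — is the regulation *plus* its
concrete sign pattern, so the same edge observed as (+1, +1) in one sample
and (-1, -1) in another yields two different instances; they are never
merged downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .network import Effect, Regulation, RegulatoryNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "RegulationInstance",
    "SampleNetwork",
    "induce_sample_network",
    "induce_all",
    "write_sample_network",
    "write_instances_long",
]


@dataclass(frozen=True)
class RegulationInstance:
    """A regulation together with the observed sign pattern of its genes.

    States are nonzero and consistent with the effect: activation implies
    ``source_state == target_state``, inhibition implies opposite states.
    ``target_state`` is implied by the invariant but stored for clarity;
    identity is the full quadruple.
    """

    regulation: Regulation
    source_state: int
    target_state: int

    def __post_init__(self) -> None:
        if self.source_state not in (-1, 1) or self.target_state not in (-1, 1):
            raise ValueError(
                "instance states must be -1 or +1, got "
                f"({self.source_state}, {self.target_state})"
            )
        if self.regulation.effect is Effect.ACTIVATION:
            if self.source_state != self.target_state:
                raise ValueError(
                    f"activation {self.regulation} requires equal states"
                )
        elif self.source_state != -self.target_state:
            raise ValueError(
                f"inhibition {self.regulation} requires opposite states"
            )

    @property
    def source(self) -> str:
        return self.regulation.source

    @property
    def target(self) -> str:
        return self.regulation.target

    @property
    def effect(self) -> Effect:
        return self.regulation.effect

    @property
    def sort_key(self) -> tuple[str, str, str, int]:
        return (*self.regulation.sort_key, self.source_state)

    def flipped(self) -> "RegulationInstance":
        """The same regulation with both gene states negated."""
        return RegulationInstance(
            self.regulation, -self.source_state, -self.target_state
        )

    def __str__(self) -> str:
        fmt = {1: "+1", -1: "-1"}
        return (
            f"{self.source}({fmt[self.source_state]}) "
            f"{'->' if self.effect is Effect.ACTIVATION else '-|'} "
            f"{self.target}({fmt[self.target_state]})"
        )


@dataclass(frozen=True)
class SampleNetwork:
    """The sign-consistent regulation instances of one sample."""

    sample_id: str
    instances: frozenset[RegulationInstance]

    def __post_init__(self) -> None:
        object.__setattr__(self, "instances", frozenset(self.instances))

    def __len__(self) -> int:
        return len(self.instances)

    def __iter__(self):
        return iter(self.instances)


def _consistent(effect: Effect, a: int, b: int) -> bool:
    if a == 0 or b == 0:
        return False
    return a == b if effect is Effect.ACTIVATION else a == -b


def induce_sample_network(
    net: RegulatoryNetwork, ind: pd.DataFrame, sample_id: str
) -> SampleNetwork:
    """Overlay one sample's indicator column on the prior network.

    Network genes absent from the indicator matrix are treated as state 0
    and can never support an instance.
    """
    if sample_id not in ind.columns:
        raise KeyError(f"unknown sample ID {sample_id!r}")
    col = ind[sample_id]
    instances = set()
    for reg in net:
        a = int(col.get(reg.source, 0))
        b = int(col.get(reg.target, 0))
        if _consistent(reg.effect, a, b):
            instances.add(RegulationInstance(reg, a, b))
    return SampleNetwork(sample_id, frozenset(instances))


def induce_all(net: RegulatoryNetwork, ind: pd.DataFrame) -> list[SampleNetwork]:
    """Induce one :class:`SampleNetwork` per indicator column, in order.

    Vectorised over samples: for each regulation the consistency rule is
    evaluated on whole state rows at once. Warns once about network genes
    missing from the indicator matrix and about self-inhibition edges, which
    can never be sign-consistent (a gene cannot oppose its own state).
    """
    if ind.shape[1] == 0:
        raise ValueError("indicator matrix has no samples")
    missing = net.gene_universe - set(ind.index)
    if missing:
        logger.warning(
            "induce_all: %d network gene(s) absent from the indicator matrix "
            "(treated as unchanged)", len(missing)
        )
    dead = [r for r in net if r.is_self_loop and r.effect is Effect.INHIBITION]
    if dead:
        logger.warning(
            "induce_all: %d self-inhibition edge(s) are structurally dead "
            "(a gene cannot have the opposite of its own state)", len(dead)
        )

    n_samples = ind.shape[1]
    zeros = np.zeros(n_samples, dtype=np.int8)
    per_sample: list[set[RegulationInstance]] = [set() for _ in range(n_samples)]
    index_pos = {g: i for i, g in enumerate(ind.index)}
    values = ind.to_numpy(dtype=np.int8)
    for reg in net.sorted_regulations():
        si = index_pos.get(reg.source)
        ti = index_pos.get(reg.target)
        a = values[si] if si is not None else zeros
        b = values[ti] if ti is not None else zeros
        if reg.effect is Effect.ACTIVATION:
            mask = (a != 0) & (a == b)
        else:
            mask = (a != 0) & (b != 0) & (a == -b)
        for j in np.flatnonzero(mask):
            per_sample[j].add(RegulationInstance(reg, int(a[j]), int(b[j])))

    nets = [
        SampleNetwork(sid, frozenset(inst))
        for sid, inst in zip(ind.columns, per_sample)
    ]
    for sn in nets:
        logger.debug("sample %s: %d instance(s)", sn.sample_id, len(sn))
    return nets


def write_sample_network(
    snet: SampleNetwork, states: pd.Series, out_dir: str | Path
) -> None:
    """Export one sample network as SIF3 plus a gene-state attribute TSV.

    ``states`` is the sample's indicator column (used to annotate nodes).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    insts = sorted(snet.instances, key=lambda i: i.sort_key)
    with (out_dir / f"{snet.sample_id}.sif").open("w") as fh:
        for i in insts:
            fh.write(f"{i.source}\t{i.effect.value}\t{i.target}\n")
    genes = sorted({g for i in insts for g in (i.source, i.target)})
    with (out_dir / f"{snet.sample_id}.nodes.tsv").open("w") as fh:
        fh.write("gene\tstate\n")
        for g in genes:
            fh.write(f"{g}\t{int(states.get(g, 0))}\n")


def write_instances_long(
    nets: list[SampleNetwork], path: str | Path
) -> None:
    """Write all samples' instances as one long-format TSV."""
    with Path(path).open("w") as fh:
        fh.write("sample\tsource\teffect\ttarget\tsource_state\ttarget_state\n")
        for sn in nets:
            for i in sorted(sn.instances, key=lambda x: x.sort_key):
                fh.write(
                    f"{sn.sample_id}\t{i.source}\t{i.effect.value}\t{i.target}"
                    f"\t{i.source_state}\t{i.target_state}\n"
                )
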