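"""Core regulations: frequency thresholding, subnetworks, comparison.

A *core regulation* of a phenotype group is a regulation instance — edge plus
sign pattern — present identically in at least a fraction T of the group's
sample networks (T = 0.5 for discovery, with T = 0.4 the usual convention
for small validation cohorts). "Identical" operates at the instance level:
the same edge observed with the opposite sign pattern counts as a different
regulation. The denominator of the frequency is the whole group, including
samples whose network is empty.

Core sets decompose into *subnetworks*: connected components of the
undirected graph whose edges are the core instances' regulations.
"""

from __future__ import annotations

import logging
from collections import Counter
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field, replace
from pathlib import Path

import networkx as nx
import pandas as pd

from .network import Effect, Regulation
from .sample_networks import RegulationInstance, SampleNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "FrequencyTable",
    "CoreRegulationSet",
    "frequency_table",
    "identify_core",
    "find_subnetworks",
    "group_specific",
    "cross_cohort_validate",
    "ValidationResult",
    "regulation_expression",
    "t_sweep",
    "write_core_set",
    "read_core_tsv",
]


@dataclass(frozen=True)
class FrequencyTable:
    """Per-instance occurrence counts across a group's sample networks.

    ``group_size`` counts every sample in the group, including those with an
    empty network; instance frequency is count / group_size. Instances absent
    from every sample do not appear.
    """

    counts: Mapping[RegulationInstance, int]
    group_size: int

    def __post_init__(self) -> None:
        if self.group_size <= 0:
            raise ValueError("group_size must be positive")
        bad = {i: c for i, c in self.counts.items()
               if not 0 < c <= self.group_size}
        if bad:
            raise ValueError(f"counts out of (0, group_size] range: {bad}")

    def frequency(self, instance: RegulationInstance) -> float:
        return self.counts.get(instance, 0) / self.group_size

    @property
    def frequencies(self) -> dict[RegulationInstance, float]:
        return {i: c / self.group_size for i, c in self.counts.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "source": i.source,
                "effect": i.effect.value,
                "target": i.target,
                "source_state": i.source_state,
                "target_state": i.target_state,
                "count": c,
                "frequency": c / self.group_size,
            }
            for i, c in sorted(self.counts.items(), key=lambda kv: kv[0].sort_key)
        ]
        return pd.DataFrame(
            rows,
            columns=["source", "effect", "target", "source_state",
                     "target_state", "count", "frequency"],
        )


@dataclass(frozen=True)
class CoreRegulationSet:
    """Regulation instances whose group frequency reaches the threshold T.

    ``component_id`` maps each instance to its subnetwork label once
    :func:`find_subnetworks` has run: contiguous integers from 1, ordered by
    decreasing component gene count, ties broken by the lexicographically
    smallest member gene.
    """

    instances: frozenset[RegulationInstance]
    threshold: float
    group_label: str | None
    frequencies: Mapping[RegulationInstance, float]
    counts: Mapping[RegulationInstance, int] = field(default_factory=dict)
    component_id: Mapping[RegulationInstance, int] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "instances", frozenset(self.instances))
        low = [i for i in self.instances
               if self.frequencies.get(i, 0.0) < self.threshold]
        if low:
            raise ValueError(
                f"{len(low)} instance(s) fall below threshold {self.threshold}"
            )

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(
            g for i in self.instances for g in (i.source, i.target)
        )

    @property
    def n_components(self) -> int:
        if self.component_id is None:
            raise AttributeError(
                "components not computed; call find_subnetworks first"
            )
        return len(set(self.component_id.values()))

    def edges(self) -> frozenset[Regulation]:
        return frozenset(i.regulation for i in self.instances)

    def __len__(self) -> int:
        return len(self.instances)

    def __iter__(self):
        return iter(sorted(self.instances, key=lambda i: i.sort_key))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i in self:
            rows.append(
                {
                    "source": i.source,
                    "effect": i.effect.value,
                    "target": i.target,
                    "source_state": i.source_state,
                    "target_state": i.target_state,
                    "count": self.counts.get(i, pd.NA),
                    "frequency": self.frequencies[i],
                    "component_id": (
                        self.component_id[i] if self.component_id else pd.NA
                    ),
                }
            )
        return pd.DataFrame(
            rows,
            columns=["source", "effect", "target", "source_state",
                     "target_state", "count", "frequency", "component_id"],
        )


def frequency_table(nets: Sequence[SampleNetwork]) -> FrequencyTable:
    """Tally each distinct regulation instance across sample networks."""
    nets = list(nets)
    if not nets:
        raise ValueError("cannot build a frequency table from zero samples")
    counts: Counter[RegulationInstance] = Counter()
    for sn in nets:
        counts.update(sn.instances)
    return FrequencyTable(dict(counts), group_size=len(nets))


def identify_core(
    freq: FrequencyTable, T: float = 0.5, group_label: str | None = None
) -> CoreRegulationSet:
    """Instances with frequency >= T ("at least T% of the total samples").

    The comparison is inclusive. T = 0.5 is the usual discovery setting;
    T = 0.4 the convention for small or heterogeneous validation cohorts.
    """
    if not 0 < T <= 1:
        raise ValueError(f"threshold T must be in (0, 1], got {T}")
    kept = frozenset(
        i for i, c in freq.counts.items() if c / freq.group_size >= T
    )
    return CoreRegulationSet(
        instances=kept,
        threshold=T,
        group_label=group_label,
        frequencies={i: freq.frequency(i) for i in kept},
        counts={i: freq.counts[i] for i in kept},
    )


def find_subnetworks(core: CoreRegulationSet) -> CoreRegulationSet:
    """Label each core instance with its connected-component subnetwork.

    Components are taken in the undirected graph on genes whose edges are the
    core instances' regulations. Labels are 1..n_components, assigned by
    decreasing component gene count, ties broken by smallest gene.
    """
    g = nx.Graph()
    for inst in core.instances:
        g.add_edge(inst.source, inst.target)
    components = sorted(
        (sorted(c) for c in nx.connected_components(g)),
        key=lambda genes: (-len(genes), genes[0]),
    )
    gene_to_comp = {
        gene: cid
        for cid, genes in enumerate(components, start=1)
        for gene in genes
    }
    component_id = {i: gene_to_comp[i.source] for i in core.instances}
    logger.info(
        "find_subnetworks: %d instance(s) in %d subnetwork(s)",
        len(core.instances), len(components),
    )
    return replace(core, component_id=component_id)


def group_specific(
    core_target: CoreRegulationSet,
    core_others: Iterable[CoreRegulationSet],
    edge_level: bool = False,
) -> frozenset[RegulationInstance]:
    """Core instances of the target group absent from every other group.

    Specificity is at the instance level by default: the same edge carried
    with a different sign pattern by another group does *not* disqualify a
    target instance. ``edge_level=True`` switches to the stricter edge-level
    comparison (any sign pattern elsewhere disqualifies).
    """
    others = list(core_others)
    for o in others:
        if o.threshold != core_target.threshold:
            logger.warning(
                "group_specific: comparing core sets built at different "
                "thresholds (%s vs %s)", core_target.threshold, o.threshold,
            )
    if edge_level:
        other_edges = set().union(*(o.edges() for o in others)) if others else set()
        return frozenset(
            i for i in core_target.instances if i.regulation not in other_edges
        )
    other_instances = (
        set().union(*(o.instances for o in others)) if others else set()
    )
    return frozenset(core_target.instances - other_instances)


@dataclass(frozen=True)
class ValidationResult:
    """Cross-cohort validation outcome: which discovery-core instances reach
    the validation threshold in an independent cohort."""

    validated: frozenset[RegulationInstance]
    report: pd.DataFrame


def cross_cohort_validate(
    core_discovery: CoreRegulationSet,
    cohort_nets: Sequence[SampleNetwork],
    T_validation: float = 0.4,
    edge_level: bool = False,
) -> ValidationResult:
    """Validate a discovery core set against an independent cohort.

    The validation cohort's core set is computed at ``T_validation`` and
    intersected with the discovery set at the instance level (or edge level
    with ``edge_level=True``). The report lists, for every discovery
    instance, its discovery frequency, its frequency in the validation
    cohort, and whether it validated. Composition across several validation
    cohorts ("validated in one or both") is caller logic via set union or
    intersection of the ``validated`` sets.
    """
    if not cohort_nets:
        raise ValueError("validation cohort is empty")
    freq_val = frequency_table(cohort_nets)
    core_val = identify_core(freq_val, T_validation)
    if edge_level:
        val_edges = core_val.edges()
        validated = frozenset(
            i for i in core_discovery.instances if i.regulation in val_edges
        )
    else:
        validated = frozenset(core_discovery.instances & core_val.instances)
    rows = []
    for i in sorted(core_discovery.instances, key=lambda x: x.sort_key):
        rows.append(
            {
                "source": i.source,
                "effect": i.effect.value,
                "target": i.target,
                "source_state": i.source_state,
                "target_state": i.target_state,
                "discovery_frequency": core_discovery.frequencies[i],
                "validation_frequency": freq_val.frequency(i),
                "validated": i in validated,
            }
        )
    report = pd.DataFrame(
        rows,
        columns=["source", "effect", "target", "source_state", "target_state",
                 "discovery_frequency", "validation_frequency", "validated"],
    )
    return ValidationResult(validated, report)


def regulation_expression(
    fc: pd.DataFrame, instance: RegulationInstance, sample_id: str
) -> float:
    """Expression score of a regulation in one sample: the sum of the two
    genes' log2 fold changes."""
    for gene in (instance.source, instance.target):
        if gene not in fc.index:
            raise KeyError(f"gene {gene!r} absent from the fold-change matrix")
    if sample_id not in fc.columns:
        raise KeyError(f"unknown sample ID {sample_id!r}")
    return float(fc.at[instance.source, sample_id] + fc.at[instance.target, sample_id])


def t_sweep(freq: FrequencyTable, T_grid: Iterable[float]) -> pd.DataFrame:
    """Core-set size at each threshold of a grid.

    The size sequence is non-increasing in T (asserted): raising the
    prevalence threshold can only shrink the core set.
    """
    grid = sorted(set(float(t) for t in T_grid))
    if not grid:
        raise ValueError("empty T grid")
    sizes = [len(identify_core(freq, t)) for t in grid]
    assert all(a >= b for a, b in zip(sizes, sizes[1:])), (
        "core-set size must be non-increasing in T"
    )
    return pd.DataFrame({"T": grid, "size": sizes})


def write_core_set(
    core: CoreRegulationSet,
    out_dir: str | Path,
    prefix: str = "core",
    graphml: bool = False,
) -> None:
    """Export a core set: instance TSV, SIF3 edges, node-state TSV, and
    optionally GraphML with state and component attributes."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    core.to_frame().to_csv(out_dir / f"{prefix}_regulations.tsv",
                           sep="\t", index=False)
    insts = sorted(core.instances, key=lambda i: i.sort_key)
    with (out_dir / f"{prefix}_edges.sif").open("w") as fh:
        for i in insts:
            fh.write(f"{i.source}\t{i.effect.value}\t{i.target}\n")
    # a gene can appear with both states across instances; export each state seen
    states: dict[str, set[int]] = {}
    for i in insts:
        states.setdefault(i.source, set()).add(i.source_state)
        states.setdefault(i.target, set()).add(i.target_state)
    with (out_dir / f"{prefix}_nodes.tsv").open("w") as fh:
        fh.write("gene\tstates\n")
        for g in sorted(states):
            fh.write(f"{g}\t{','.join(str(s) for s in sorted(states[g]))}\n")
    if graphml:
        g = nx.MultiDiGraph()
        for gene, ss in sorted(states.items()):
            g.add_node(gene, states=",".join(str(s) for s in sorted(ss)))
        for i in insts:
            g.add_edge(
                i.source, i.target,
                effect=i.effect.value,
                source_state=i.source_state,
                target_state=i.target_state,
                frequency=core.frequencies[i],
                component=(core.component_id[i] if core.component_id else 0),
            )
        nx.write_graphml(g, out_dir / f"{prefix}.graphml")


def read_core_tsv(path: str | Path, threshold: float | None = None,
                  group_label: str | None = None) -> CoreRegulationSet:
    """Read a core-regulation TSV written by :func:`write_core_set`."""
    df = pd.read_csv(path, sep="\t")
    instances = {}
    counts = {}
    comp: dict[RegulationInstance, int] = {}
    for _, row in df.iterrows():
        reg = Regulation(str(row["source"]), str(row["target"]),
                         Effect(row["effect"]))
        inst = RegulationInstance(reg, int(row["source_state"]),
                                  int(row["target_state"]))
        instances[inst] = float(row["frequency"])
        if pd.notna(row.get("count")):
            counts[inst] = int(row["count"])
        if "component_id" in df.columns and pd.notna(row["component_id"]):
            comp[inst] = int(row["component_id"])
    if threshold is None:
        threshold = min(instances.values(), default=1.0)
    return CoreRegulationSet(
        instances=frozenset(instances),
        threshold=threshold,
        group_label=group_label,
        frequencies=instances,
        counts=counts,
        component_id=comp or None,
    )
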