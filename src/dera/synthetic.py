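"""Synthetic cohorts with planted, sign-consistent regulations.

The generator emulates the data structure the method assumes: a signed prior
network, log2-scale expression for reference (control) samples and for one
or more phenotype groups, and ground-truth "planted" regulation instances
occurring at a controlled per-group prevalence.

Model: every entry starts at a common baseline with independent Gaussian
noise on the log2 scale (array-style log-intensity noise). Each planted
instance assigned to a group (or shared by all groups) is activated per
sample as an independent Bernoulli(p) event; when active, its source gene is
shifted by ``source_state * effect_size_log2`` and its target by
``target_state * effect_size_log2``. With the default effect size of 2 and
noise SD of 0.3, an active gene exceeds the two-fold cutoff with probability
> 0.999 (the margin is more than 3 noise SDs), so the observed instance
prevalence tracks the nominal p.

Regeneration from the same spec is bit-exact: a single seed drives all
randomness through deterministic child streams (network topology, planting
choices, expression noise).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .expression import REFERENCE_LABEL
from .network import Effect, Regulation, RegulatoryNetwork, write_network
from .sample_networks import RegulationInstance

__all__ = [
    "PlantedInstance",
    "SyntheticSpec",
    "SyntheticCohort",
    "generate",
    "network_for_spec",
    "make_planted_spec",
    "spec_from_yaml",
    "write_cohort",
]

#: Group label meaning "planted in every phenotype group".
SHARED = "shared"

# fixed child-stream tags so network / planting / expression draws never interleave
_NET_STREAM, _PLANT_STREAM, _EXPR_STREAM = 0, 1, 2


@dataclass(frozen=True)
class PlantedInstance:
    """A ground-truth regulation instance planted at a nominal prevalence in
    one group (or in every group when ``group == "shared"``)."""

    instance: RegulationInstance
    group: str
    prevalence: float

    def __post_init__(self) -> None:
        if not 0 <= self.prevalence <= 1:
            raise ValueError(f"prevalence must be in [0, 1], got {self.prevalence}")


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic cohort.

    ``groups`` lists (label, n_samples) pairs; ``n_reference`` control
    samples are always generated. ``effect_size_log2`` is the absolute log2
    fold change injected into an active planted gene (default 2.0, i.e. a
    four-fold change — comfortably past the two-fold cutoff);
    ``noise_sd_log2`` the per-entry Gaussian noise SD (default 0.3).
    ``network_seed`` pins the topology independently of ``seed`` so that
    cohorts re-drawn with a new seed share the same network and planted
    truth; by default it follows ``seed``.
    """

    n_genes: int = 30
    n_edges: int = 50
    inhibition_fraction: float = 0.3
    groups: tuple[tuple[str, int], ...] = (("TUMOR", 40),)
    n_reference: int = 10
    planted: tuple[PlantedInstance, ...] = ()
    effect_size_log2: float = 2.0
    noise_sd_log2: float = 0.3
    baseline_log2: float = 7.0
    seed: int = 0
    network_seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_genes < 2:
            raise ValueError("need at least 2 genes")
        if not 0 < self.n_edges <= self.n_genes * (self.n_genes - 1):
            raise ValueError("n_edges out of range for a simple directed graph")
        if not 0 <= self.inhibition_fraction <= 1:
            raise ValueError("inhibition_fraction must be in [0, 1]")
        if self.n_reference < 1:
            raise ValueError("need at least one reference sample")
        if self.effect_size_log2 <= 0 or self.noise_sd_log2 <= 0:
            raise ValueError("effect size and noise SD must be positive")
        labels = [g for g, _ in self.groups]
        if len(labels) != len(set(labels)) or REFERENCE_LABEL in labels:
            raise ValueError("group labels must be unique and not the "
                             "reserved reference label")
        for p in self.planted:
            if p.group != SHARED and p.group not in labels:
                raise ValueError(f"planted group {p.group!r} not in spec groups")


@dataclass(frozen=True)
class SyntheticCohort:
    """A generated cohort: network, log2 expression, phenotype labels, and
    the planted ground truth."""

    spec: SyntheticSpec
    network: RegulatoryNetwork
    expression: pd.DataFrame  # genes x samples, log2 scale
    phenotype: pd.Series      # sample -> group (REFERENCE for controls)
    planted: tuple[PlantedInstance, ...]

    @property
    def reference_ids(self) -> list[str]:
        return list(self.phenotype.index[self.phenotype == REFERENCE_LABEL])

    def tumor_ids(self, group: str | None = None) -> list[str]:
        mask = self.phenotype != REFERENCE_LABEL
        if group is not None:
            mask = self.phenotype == group
        return list(self.phenotype.index[mask])

    def truth(self, T: float = 0.5) -> dict[str, frozenset[RegulationInstance]]:
        """Planted instances with nominal prevalence >= T, per group."""
        out: dict[str, set[RegulationInstance]] = {
            g: set() for g, _ in self.spec.groups
        }
        for p in self.planted:
            if p.prevalence >= T:
                targets = out if p.group == SHARED else {p.group: out[p.group]}
                for s in targets.values():
                    s.add(p.instance)
        return {g: frozenset(s) for g, s in out.items()}


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), stream]))


def _gene_names(n: int) -> list[str]:
    return [f"G{i:04d}" for i in range(1, n + 1)]


def network_for_spec(spec: SyntheticSpec) -> RegulatoryNetwork:
    """The (deterministic) random network a spec induces.

    A simple directed graph: ``n_edges`` distinct ordered gene pairs without
    self-loops, each inhibitory with probability ``inhibition_fraction``.
    """
    seed = spec.network_seed if spec.network_seed is not None else spec.seed
    rng = _rng(seed, _NET_STREAM)
    genes = _gene_names(spec.n_genes)
    n = spec.n_genes
    pair_idx = rng.choice(n * (n - 1), size=spec.n_edges, replace=False)
    regulations = set()
    for k in sorted(int(i) for i in pair_idx):
        i, j = divmod(k, n - 1)
        if j >= i:
            j += 1  # skip the diagonal
        effect = (
            Effect.INHIBITION
            if rng.random() < spec.inhibition_fraction
            else Effect.ACTIVATION
        )
        regulations.add(Regulation(genes[i], genes[j], effect))
    return RegulatoryNetwork(frozenset(regulations))


def generate(spec: SyntheticSpec) -> SyntheticCohort:
    """Generate a cohort from a spec (bit-exact under a fixed seed)."""
    network = network_for_spec(spec)
    for p in spec.planted:
        if p.instance.regulation not in network:
            raise ValueError(
                f"planted instance {p.instance} is not embeddable: its "
                "regulation is absent from the generated network"
            )

    genes = _gene_names(spec.n_genes)
    gene_pos = {g: i for i, g in enumerate(genes)}
    ref_ids = [f"REF_{i:03d}" for i in range(1, spec.n_reference + 1)]
    sample_ids = list(ref_ids)
    labels = [REFERENCE_LABEL] * spec.n_reference
    for label, n_samples in spec.groups:
        sample_ids += [f"{label}_{i:03d}" for i in range(1, n_samples + 1)]
        labels += [label] * n_samples

    rng = _rng(spec.seed, _EXPR_STREAM)
    values = spec.baseline_log2 + rng.normal(
        0.0, spec.noise_sd_log2, size=(spec.n_genes, len(sample_ids))
    )
    # planted shifts: per-sample, per-instance independent Bernoulli(p)
    for col, group in enumerate(labels):
        if group == REFERENCE_LABEL:
            continue
        for p in spec.planted:
            if p.group not in (SHARED, group):
                continue
            if rng.random() < p.prevalence:
                inst = p.instance
                values[gene_pos[inst.source], col] += (
                    inst.source_state * spec.effect_size_log2
                )
                values[gene_pos[inst.target], col] += (
                    inst.target_state * spec.effect_size_log2
                )

    expression = pd.DataFrame(values, index=genes, columns=sample_ids)
    phenotype = pd.Series(labels, index=sample_ids, name="group")
    return SyntheticCohort(spec, network, expression, phenotype, spec.planted)


def _select_planted_edges(
    network: RegulatoryNetwork,
    rng: np.random.Generator,
    n_isolated: int,
    n_decoys: int,
) -> tuple[list[Regulation], list[Regulation]] | None:
    """Choose edges whose planting leaves the ground truth unambiguous.

    The first ``n_isolated`` edges (for high-prevalence instances) are chosen
    so that no *other* network edge touches any of their genes: two planted
    instances active in the same samples could otherwise drive an un-planted
    edge between their genes past the core threshold. Decoy edges only need
    to be vertex-disjoint from every planted gene — their low prevalence
    makes incidental co-activation with neighbours statistically negligible.

    Returns None when the topology cannot host the request.
    """
    adjacency: dict[str, set[str]] = {}
    pair_count: dict[frozenset[str], int] = {}
    for r in network:
        adjacency.setdefault(r.source, set()).add(r.target)
        adjacency.setdefault(r.target, set()).add(r.source)
        key = frozenset((r.source, r.target))
        pair_count[key] = pair_count.get(key, 0) + 1
    candidates = sorted(
        (
            r for r in network
            if not r.is_self_loop
            and pair_count[frozenset((r.source, r.target))] == 1
        ),
        key=lambda r: r.sort_key,
    )
    rng.shuffle(candidates)  # type: ignore[arg-type]
    # low-degree edges first: they are easiest to isolate (stable sort keeps
    # the shuffled order within equal degree sums)
    candidates.sort(key=lambda r: len(adjacency[r.source]) + len(adjacency[r.target]))

    chosen: list[Regulation] = []
    planted_genes: set[str] = set()
    budget = [200_000]  # backtracking cap; networks this size never get close

    def backtrack(start: int) -> bool:
        if len(chosen) == n_isolated:
            return True
        if budget[0] <= 0:
            return False
        for j in range(start, len(candidates)):
            budget[0] -= 1
            r = candidates[j]
            u, v = r.source, r.target
            if (
                u in planted_genes or v in planted_genes
                or adjacency[u] & planted_genes
                or adjacency[v] & planted_genes
            ):
                continue
            chosen.append(r)
            planted_genes.update((u, v))
            if backtrack(j + 1):
                return True
            chosen.pop()
            planted_genes.difference_update((u, v))
        return False

    if not backtrack(0):
        return None
    decoys: list[Regulation] = []
    for r in candidates:
        if len(decoys) == n_decoys:
            break
        if r in chosen or r.source in planted_genes or r.target in planted_genes:
            continue
        decoys.append(r)
        planted_genes.update((r.source, r.target))
    if len(decoys) < n_decoys:
        return None
    return chosen, decoys


def _random_instance(reg: Regulation, rng: np.random.Generator) -> RegulationInstance:
    s = 1 if rng.random() < 0.5 else -1
    t = s if reg.effect is Effect.ACTIVATION else -s
    return RegulationInstance(reg, s, t)


def make_planted_spec(
    seed: int,
    *,
    groups: tuple[tuple[str, int], ...] = (("TUMOR", 40),),
    n_reference: int = 10,
    n_genes: int = 30,
    n_edges: int = 50,
    inhibition_fraction: float = 0.3,
    n_shared_signal: int = 5,
    signal_prevalence: float = 0.7,
    n_shared_decoys: int = 5,
    decoy_prevalence: float = 0.2,
    n_private_per_group: int = 0,
    private_prevalence: float = 0.8,
    effect_size_log2: float = 2.0,
    noise_sd_log2: float = 0.3,
) -> SyntheticSpec:
    """Build a spec whose planted instances make ground truth unambiguous.

    High-prevalence instances — the shared signal at ``signal_prevalence``
    and any per-group private instances at ``private_prevalence`` — are
    planted on edges whose genes touch no other network edge, so the planted
    shifts can never drive an un-planted regulation past the core threshold.
    Decoy instances at ``decoy_prevalence`` are vertex-disjoint from all
    planted genes. Topologies that cannot host the request are redrawn (the
    network seed is advanced deterministically), so regeneration from the
    returned spec remains bit-exact.
    """
    n_isolated = n_shared_signal + n_private_per_group * len(groups)
    last_error = None
    for attempt in range(64):
        net_seed = (
            seed if attempt == 0
            else int(np.random.SeedSequence([seed, 900 + attempt])
                     .generate_state(1)[0])
        )
        base = SyntheticSpec(
            n_genes=n_genes,
            n_edges=n_edges,
            inhibition_fraction=inhibition_fraction,
            groups=groups,
            n_reference=n_reference,
            effect_size_log2=effect_size_log2,
            noise_sd_log2=noise_sd_log2,
            seed=seed,
            network_seed=net_seed,
        )
        network = network_for_spec(base)
        rng = _rng(seed, _PLANT_STREAM)
        selection = _select_planted_edges(network, rng, n_isolated,
                                          n_shared_decoys)
        if selection is not None:
            break
        last_error = (
            f"cannot plant {n_isolated} isolated + {n_shared_decoys} decoy "
            f"instances in a {n_genes}-gene / {n_edges}-edge network"
        )
    else:
        raise ValueError(f"{last_error}; increase n_genes or lower n_edges")

    isolated, decoys = selection
    planted: list[PlantedInstance] = []
    it = iter(isolated)
    for _ in range(n_shared_signal):
        planted.append(
            PlantedInstance(_random_instance(next(it), rng), SHARED,
                            signal_prevalence)
        )
    for label, _n in groups:
        for _ in range(n_private_per_group):
            planted.append(
                PlantedInstance(_random_instance(next(it), rng), label,
                                private_prevalence)
            )
    for reg in decoys:
        planted.append(
            PlantedInstance(_random_instance(reg, rng), SHARED,
                            decoy_prevalence)
        )
    return dataclasses.replace(base, planted=tuple(planted))


def spec_from_yaml(path: str | Path) -> SyntheticSpec:
    """Load a :class:`SyntheticSpec` from a YAML file.

    Two planting styles are supported. Explicit ``planted`` entries name a
    network edge, a sign pattern, a group (or "shared") and a prevalence;
    they must refer to edges of the generated network. Alternatively an
    ``auto_planted`` block (keys mirroring :func:`make_planted_spec`:
    ``n_shared_signal``, ``signal_prevalence``, ``n_shared_decoys``,
    ``decoy_prevalence``, ``n_private_per_group``, ``private_prevalence``)
    lets the generator choose unambiguous edges itself.
    """
    cfg = yaml.safe_load(Path(path).read_text())
    groups = tuple(
        (str(g["label"]), int(g["n_samples"])) for g in cfg.get("groups", [])
    ) or (("TUMOR", 40),)
    common = {
        k: cfg[k]
        for k in (
            "n_genes", "n_edges", "inhibition_fraction", "n_reference",
            "effect_size_log2", "noise_sd_log2", "baseline_log2", "seed",
            "network_seed",
        )
        if k in cfg
    }
    if "auto_planted" in cfg:
        auto = dict(cfg["auto_planted"])
        common.pop("baseline_log2", None)  # make_planted_spec keeps the default
        common.pop("network_seed", None)
        return make_planted_spec(
            int(cfg.get("seed", 0)),
            groups=groups,
            **{k: v for k, v in common.items() if k != "seed"},
            **auto,
        )
    planted = tuple(
        PlantedInstance(
            RegulationInstance(
                Regulation(
                    str(p["source"]), str(p["target"]), Effect(p["effect"])
                ),
                int(p["source_state"]),
                int(p.get(
                    "target_state",
                    p["source_state"]
                    if Effect(p["effect"]) is Effect.ACTIVATION
                    else -p["source_state"],
                )),
            ),
            str(p.get("group", SHARED)),
            float(p["prevalence"]),
        )
        for p in cfg.get("planted", [])
    )
    return SyntheticSpec(groups=groups, planted=planted, **common)


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> None:
    """Write a cohort as network SIF3, expression TSV, phenotype TSV and a
    ground-truth TSV of planted instances."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_network(cohort.network, out_dir / "network.sif")
    cohort.expression.to_csv(out_dir / "expression.tsv", sep="\t",
                             index_label="gene")
    cohort.phenotype.rename_axis("sample_id").to_csv(
        out_dir / "phenotype.tsv", sep="\t", header=False
    )
    with (out_dir / "truth.tsv").open("w") as fh:
        fh.write("source\teffect\ttarget\tsource_state\ttarget_state"
                 "\tgroup\tprevalence\n")
        for p in sorted(cohort.planted,
                        key=lambda x: (x.group, x.instance.sort_key)):
            i = p.instance
            fh.write(
                f"{i.source}\t{i.effect.value}\t{i.target}\t{i.source_state}"
                f"\t{i.target_state}\t{p.group}\t{p.prevalence}\n"
            )
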