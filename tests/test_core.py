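"""Frequency tables, core sets, subnetworks, comparison, validation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dera.core import (
    CoreRegulationSet,
    cross_cohort_validate,
    find_subnetworks,
    frequency_table,
    group_specific,
    identify_core,
    read_core_tsv,
    regulation_expression,
    t_sweep,
    write_core_set,
)
from dera.network import Effect, Regulation
from dera.sample_networks import RegulationInstance, SampleNetwork, induce_all

from conftest import random_indicator, random_network


def inst(src, tgt, effect=Effect.ACTIVATION, state=1):
    tgt_state = state if effect is Effect.ACTIVATION else -state
    return RegulationInstance(Regulation(src, tgt, effect), state, tgt_state)


def nets_from(instance_lists):
    return [
        SampleNetwork(f"s{j}", frozenset(insts))
        for j, insts in enumerate(instance_lists)
    ]


class TestFrequencyTable:
    def test_counts_and_frequencies(self):
        i1 = inst("A", "B")
        nets = nets_from([[i1], [i1], [], []])
        ft = frequency_table(nets)
        assert ft.group_size == 4
        assert ft.counts[i1] == 2
        assert ft.frequency(i1) == 0.5

    def test_instance_in_every_sample_has_frequency_one(self):
        i1 = inst("A", "B")
        ft = frequency_table(nets_from([[i1]] * 3))
        assert ft.frequency(i1) == 1.0

    def test_empty_group_is_an_error(self):
        with pytest.raises(ValueError):
            frequency_table([])

    def test_empty_networks_count_in_denominator(self):
        i1 = inst("A", "B")
        ft = frequency_table(nets_from([[i1], [], [], [], []]))
        assert ft.frequency(i1) == pytest.approx(0.2)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=20, deadline=None)
    def test_matches_nested_iteration_tally(self, seed):
        rng = np.random.default_rng(seed)
        net = random_network(rng, 20, 30)
        ind = random_indicator(rng, sorted(net.gene_universe), 20)
        nets = induce_all(net, ind)
        ft = frequency_table(nets)
        tally = {}
        for sn in nets:
            for i in sn.instances:
                tally[i] = tally.get(i, 0) + 1
        assert dict(ft.counts) == tally


class TestIdentifyCore:
    def test_inclusive_boundary(self):
        e1, e2, e3 = inst("A", "B"), inst("C", "D"), inst("E", "F")
        nets = nets_from([
            [e1, e2], [e1, e2], [e1], [e1, e3],
            [e1, e2], [e1, e2, e3], [e1], [e1, e2],
            [e2], [e3, e1],
        ])
        ft = frequency_table(nets)
        assert ft.frequency(e1) == 0.9
        assert ft.frequency(e2) == 0.6
        assert ft.frequency(e3) == 0.3
        core = identify_core(ft, 0.6)
        assert core.instances == {e1, e2}

    def test_threshold_one_keeps_only_universal_instances(self):
        i1, i2 = inst("A", "B"), inst("C", "D")
        ft = frequency_table(nets_from([[i1, i2], [i1]]))
        assert identify_core(ft, 1.0).instances == {i1}

    @pytest.mark.parametrize("T", [0.0, -0.1, 1.5])
    def test_threshold_outside_unit_interval_rejected(self, T):
        ft = frequency_table(nets_from([[inst("A", "B")]]))
        with pytest.raises(ValueError):
            identify_core(ft, T)

    @given(seed=st.integers(0, 10_000),
           t_pair=st.tuples(st.floats(0.05, 1.0), st.floats(0.05, 1.0)))
    @settings(max_examples=20, deadline=None)
    def test_threshold_monotonicity(self, seed, t_pair):
        t1, t2 = sorted(t_pair)
        rng = np.random.default_rng(seed)
        net = random_network(rng, 15, 25)
        ind = random_indicator(rng, sorted(net.gene_universe), 12)
        ft = frequency_table(induce_all(net, ind))
        assert identify_core(ft, t2).instances <= identify_core(ft, t1).instances


class TestSubnetworks:
    def test_textbook_components(self):
        core = identify_core(
            frequency_table(nets_from([[inst("A", "B"), inst("B", "C"),
                                        inst("D", "E")]])),
            0.5,
        )
        core = find_subnetworks(core)
        assert core.n_components == 2
        # larger component {A,B,C} gets label 1
        assert core.component_id[inst("A", "B")] == 1
        assert core.component_id[inst("B", "C")] == 1
        assert core.component_id[inst("D", "E")] == 2

    def test_empty_core_has_zero_components(self):
        ft = frequency_table(nets_from([[inst("A", "B")], [], []]))
        core = find_subnetworks(identify_core(ft, 0.9))
        assert len(core) == 0 and core.n_components == 0

    def test_tie_broken_by_smallest_gene(self):
        core = identify_core(
            frequency_table(nets_from([[inst("X", "Y"), inst("A", "B")]])), 0.5
        )
        core = find_subnetworks(core)
        assert core.component_id[inst("A", "B")] == 1
        assert core.component_id[inst("X", "Y")] == 2

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_matches_union_find_and_conserves_edges(self, seed):
        rng = np.random.default_rng(seed)
        net = random_network(rng, 25, 50)
        regs = sorted(net.regulations, key=lambda r: r.sort_key)
        chosen = [r for r in regs if rng.random() < 0.5 and not r.is_self_loop]
        insts = [inst(r.source, r.target, r.effect,
                      1 if rng.random() < 0.5 else -1) for r in chosen]
        core = find_subnetworks(identify_core(
            frequency_table(nets_from([insts])), 0.5))
        # brute-force union-find over the same edges
        parent = {g: g for i in insts for g in (i.source, i.target)}

        def find(x):
            while parent[x] != x:
                x = parent[x]
            return x

        for i in insts:
            parent[find(i.source)] = find(i.target)
        partition = {}
        for g in parent:
            partition.setdefault(find(g), set()).add(g)
        expected = {frozenset(v) for v in partition.values()}
        got = {}
        for i, cid in core.component_id.items():
            got.setdefault(cid, set()).update((i.source, i.target))
        assert {frozenset(v) for v in got.values()} == expected
        # edge counts across components sum to the core size
        assert sum(
            sum(1 for i in core.instances if core.component_id[i] == cid)
            for cid in set(core.component_id.values())
        ) == len(core)


class TestGroupSpecific:
    def test_set_difference(self):
        i1, i2 = inst("A", "B"), inst("C", "D")
        target = identify_core(frequency_table(nets_from([[i1, i2]])), 0.5)
        other = identify_core(frequency_table(nets_from([[i2]])), 0.5)
        empty = identify_core(frequency_table(nets_from([[]])), 0.5)
        assert group_specific(target, [other, empty]) == {i1}

    def test_empty_others_keep_target(self):
        i1 = inst("A", "B")
        target = identify_core(frequency_table(nets_from([[i1]])), 0.5)
        assert group_specific(target, []) == {i1}

    def test_opposite_sign_pattern_does_not_disqualify(self):
        up, down = inst("A", "B", state=1), inst("A", "B", state=-1)
        target = identify_core(frequency_table(nets_from([[up]])), 0.5)
        other = identify_core(frequency_table(nets_from([[down]])), 0.5)
        assert group_specific(target, [other]) == {up}
        assert group_specific(target, [other], edge_level=True) == frozenset()

    def test_output_disjoint_from_every_other_core(self):
        rng = np.random.default_rng(5)
        net = random_network(rng, 20, 30)
        cores = []
        for _ in range(3):
            ind = random_indicator(rng, sorted(net.gene_universe), 10, 0.6)
            cores.append(identify_core(
                frequency_table(induce_all(net, ind)), 0.3))
        specific = group_specific(cores[0], cores[1:])
        for other in cores[1:]:
            assert not (specific & other.instances)


class TestCrossCohortValidation:
    def test_threshold_and_intersection(self):
        i1, i2 = inst("A", "B"), inst("C", "D")
        discovery = identify_core(frequency_table(nets_from([[i1, i2]] * 2)), 0.5)
        # validation cohort of 20: i1 in 9 (0.45), i2 in 6 (0.30)
        val_nets = nets_from([[i1, i2]] * 6 + [[i1]] * 3 + [[]] * 11)
        result = cross_cohort_validate(discovery, val_nets, 0.4)
        assert result.validated == {i1}
        report = result.report.set_index("source")
        assert report.loc["A", "validation_frequency"] == pytest.approx(0.45)
        assert report.loc["C", "validation_frequency"] == pytest.approx(0.30)
        assert bool(report.loc["A", "validated"]) is True

    def test_self_validation_identity(self):
        rng = np.random.default_rng(6)
        net = random_network(rng, 20, 30)
        ind = random_indicator(rng, sorted(net.gene_universe), 15, 0.6)
        nets = induce_all(net, ind)
        core = identify_core(frequency_table(nets), 0.4)
        result = cross_cohort_validate(core, nets, 0.4)
        assert result.validated == core.instances

    def test_empty_validation_cohort_rejected(self):
        core = identify_core(frequency_table(nets_from([[inst("A", "B")]])), 0.5)
        with pytest.raises(ValueError):
            cross_cohort_validate(core, [], 0.4)


class TestRegulationExpression:
    def test_sum_of_two_gene_fold_changes(self):
        fc = pd.DataFrame([[1.5], [2.0]], index=["A", "B"], columns=["s"])
        assert regulation_expression(fc, inst("A", "B"), "s") == pytest.approx(3.5)

    def test_opposite_fold_changes_cancel(self):
        fc = pd.DataFrame([[1.0], [-1.0]], index=["A", "B"], columns=["s"])
        assert regulation_expression(fc, inst("A", "B"), "s") == 0.0

    def test_missing_gene_named_in_error(self):
        fc = pd.DataFrame([[1.0]], index=["A"], columns=["s"])
        with pytest.raises(KeyError, match="B"):
            regulation_expression(fc, inst("A", "B"), "s")

    def test_matches_elementwise_recomputation(self):
        rng = np.random.default_rng(7)
        net = random_network(rng, 12, 18)
        genes = sorted(net.gene_universe)
        fc = pd.DataFrame(rng.normal(size=(len(genes), 5)), index=genes,
                          columns=[f"s{j}" for j in range(5)])
        regs = [r for r in net.sorted_regulations() if not r.is_self_loop][:10]
        for r in regs:
            i = inst(r.source, r.target, r.effect)
            for s in fc.columns:
                assert regulation_expression(fc, i, s) == pytest.approx(
                    fc.at[r.source, s] + fc.at[r.target, s]
                )


class TestTSweep:
    def test_counts_above_thresholds(self):
        i1, i2, i3 = inst("A", "B"), inst("C", "D"), inst("E", "F")
        nets = nets_from(
            [[i1, i2, i3]] * 3 + [[i1, i2]] * 3 + [[i1]] * 3 + [[]]
        )
        ft = frequency_table(nets)  # freqs 0.9, 0.6, 0.3
        table = t_sweep(ft, [0.25, 0.5, 0.75])
        assert table["size"].tolist() == [3, 2, 1]

    def test_single_point_grid_matches_identify_core(self):
        ft = frequency_table(nets_from([[inst("A", "B")], []]))
        table = t_sweep(ft, [0.5])
        assert table["size"].tolist() == [len(identify_core(ft, 0.5))]

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=15, deadline=None)
    def test_matches_brute_force_recount(self, seed):
        rng = np.random.default_rng(seed)
        net = random_network(rng, 15, 25)
        ind = random_indicator(rng, sorted(net.gene_universe), 12, 0.6)
        ft = frequency_table(induce_all(net, ind))
        grid = np.linspace(0.05, 1.0, 20)
        table = t_sweep(ft, grid)
        for t, size in zip(table["T"], table["size"]):
            assert size == sum(1 for f in ft.frequencies.values() if f >= t)


class TestCoreSetContract:
    def test_below_threshold_instance_rejected(self):
        i1 = inst("A", "B")
        with pytest.raises(ValueError):
            CoreRegulationSet(
                instances=frozenset({i1}), threshold=0.5,
                group_label=None, frequencies={i1: 0.3},
            )

    def test_tsv_round_trip(self, tmp_path):
        rng = np.random.default_rng(8)
        net = random_network(rng, 15, 25)
        ind = random_indicator(rng, sorted(net.gene_universe), 10, 0.6)
        core = find_subnetworks(
            identify_core(frequency_table(induce_all(net, ind)), 0.3)
        )
        assert len(core) > 0
        write_core_set(core, tmp_path, prefix="core")
        back = read_core_tsv(tmp_path / "core_regulations.tsv", threshold=0.3)
        assert back.instances == core.instances
        assert back.component_id == core.component_id
        for i in core.instances:
            assert back.frequencies[i] == pytest.approx(core.frequencies[i])
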