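"""Frozen-input gate reduction, module isolation, mutant ensembles."""

import itertools

import numpy as np
import pytest

from mechbool.model import compile_truth_table, parse_model
from mechbool.reduction import (MutantSpec, gate_entropy,
                                generate_mutant_ensemble, isolate_module,
                                reduce_gate_frozen_inputs)
from mechbool.attractors import enumerate_attractors_exhaustive
from conftest import random_instances


def brute_force_reduction(spec, removed):
    """Independent oracle: enumerate frozen assignments directly on the
    expression, apply the functionality filter, maximize entropy, tie-break
    lexicographically."""
    remaining = [r for r in spec.regulators if r not in removed]
    removed_decl = [r for r in spec.regulators if r in removed]
    candidates = []
    for frozen in itertools.product((0, 1), repeat=len(removed_decl)):
        frozen_map = dict(zip(removed_decl, frozen))
        table = []
        for bits in itertools.product((0, 1), repeat=len(remaining)):
            env = dict(zip(remaining, bits))
            env.update(frozen_map)
            table.append(spec.evaluate(env))
        functional = True
        for j in range(len(remaining)):
            differs = False
            for bits in itertools.product((0, 1), repeat=len(remaining)):
                if bits[j] == 1:
                    continue
                flipped = list(bits)
                flipped[j] = 1
                env0 = dict(zip(remaining, bits)); env0.update(frozen_map)
                env1 = dict(zip(remaining, flipped)); env1.update(frozen_map)
                if spec.evaluate(env0) != spec.evaluate(env1):
                    differs = True
                    break
            if not differs:
                functional = False
                break
        candidates.append((frozen, tuple(table), functional))
    pool = [c for c in candidates if c[2]] or candidates
    best = max(pool, key=lambda c: (round(gate_entropy(c[1]), 12),
                                    tuple(-b for b in c[0])))
    return best[1]


class TestGateReduction:
    def test_or_gate_keeps_functional_branch(self):
        spec = compile_truth_table("G", ("B", "C"), "B or C")
        red = reduce_gate_frozen_inputs(spec, ["C"])
        assert red.regulators == ("B",)
        assert red.truth_table == (0, 1)  # C frozen OFF keeps B functional

    def test_matches_brute_force_on_random_four_input_gates(self):
        rng = np.random.default_rng(4)
        regs = ("A", "B", "C", "D")
        for _ in range(60):
            table = tuple(int(b) for b in rng.integers(0, 2, 16))
            from mechbool.reduction import _table_to_expression
            expr = _table_to_expression(regs, table)
            if expr in ("0", "1"):
                continue
            spec = compile_truth_table("G", regs, expr)
            assert spec.truth_table == table
            for removed in itertools.combinations(regs, 2):
                got = reduce_gate_frozen_inputs(spec, list(removed))
                assert got.truth_table == brute_force_reduction(spec, removed)

    def test_removing_all_regulators_freezes_to_majority(self, caplog):
        spec = compile_truth_table("G", ("A", "B"), "A or B")
        with caplog.at_level("WARNING"):
            red = reduce_gate_frozen_inputs(spec, ["A", "B"])
        assert red.regulators == () and red.truth_table == (1,)
        tie = compile_truth_table("G", ("A", "B"), "A and not B or (not A and B)")
        red = reduce_gate_frozen_inputs(tie, ["A", "B"])
        assert red.truth_table == (0,)  # tie -> OFF

    def test_entropy_is_maximal_among_functional_assignments(self):
        rng = np.random.default_rng(10)
        regs = ("A", "B", "C", "D", "E")
        from mechbool.reduction import _table_to_expression, _reduced_table, \
            _regulator_functional
        for _ in range(20):
            table = tuple(int(b) for b in rng.integers(0, 2, 32))
            expr = _table_to_expression(regs, table)
            if expr in ("0", "1"):
                continue
            spec = compile_truth_table("G", regs, expr)
            removed = ["B", "D"]
            red = reduce_gate_frozen_inputs(spec, removed)
            h_got = gate_entropy(red.truth_table)
            pos = [spec.regulators.index(r) for r in removed]
            for frozen in itertools.product((0, 1), repeat=2):
                t = _reduced_table(spec, pos, frozen)
                if all(_regulator_functional(t, 3, j) for j in range(3)):
                    assert h_got >= gate_entropy(t) - 1e-12

    def test_bad_removals_rejected(self):
        spec = compile_truth_table("G", ("A", "B"), "A or B")
        with pytest.raises(ValueError):
            reduce_gate_frozen_inputs(spec, [])
        with pytest.raises(ValueError):
            reduce_gate_frozen_inputs(spec, ["Z"])

    def test_expression_of_reduction_reproduces_its_table(self):
        spec = compile_truth_table("G", ("A", "B", "C"), "(A and B) or not C")
        red = reduce_gate_frozen_inputs(spec, ["B"])
        rebuilt = compile_truth_table(red.name, red.regulators, red.expression)
        assert rebuilt.truth_table == red.truth_table


class TestModuleIsolation:
    def test_whole_model_is_identity(self, emt_switch):
        sub = isolate_module(emt_switch, emt_switch.node_names)
        for a, b in zip(emt_switch.nodes, sub.nodes):
            assert a.truth_table == b.truth_table

    def test_isolated_module_is_self_contained(self):
        m = next(iter(random_instances(1, seed=13, max_inputs=0)))
        module = list(m.node_names[:4])
        sub = isolate_module(m, module)
        assert set(sub.node_names) == set(module)
        for spec in sub.nodes:
            assert set(spec.regulators) <= set(module)

    def test_empty_module_rejected(self, toggle):
        with pytest.raises(ValueError):
            isolate_module(toggle, [])

    def test_emt_marker_core_keeps_terminal_states_after_isolation(self, emt_switch):
        # stripping the frozen former regulators re-freezes miR-200's
        # maintenance input; the terminal epithelial and mesenchymal fixed
        # points must survive the surgery regardless
        markers = [n for n in emt_switch.node_names
                   if n not in ("NFkB", "GSK3", "c_Myb")]
        sub = isolate_module(emt_switch, markers)
        fps = [dict(zip(sub.node_names, a.states[0]))
               for a in enumerate_attractors_exhaustive(sub, {})
               if a.is_fixed_point]
        epi = [s for s in fps if s["miR_34"] and s["miR_200"]
               and s["Ecadherin_mRNA"] and not s["SNAI1"]]
        mes = [s for s in fps if not s["miR_34"] and not s["miR_200"]
               and not s["Ecadherin_mRNA"] and s["ZEB1_H"]]
        assert len(epi) == 1 and len(mes) == 1


class TestMutantEnsembles:
    def test_zero_errors_reproduces_wild_type(self, emt_switch):
        spec = MutantSpec(kind="node_lock", errors_per_network=0,
                          ensemble_size=3)
        for mut in generate_mutant_ensemble(emt_switch, spec, rng=0):
            for a, b in zip(emt_switch.nodes, mut.nodes):
                assert a.truth_table == b.truth_table

    def test_gate_flip_changes_exactly_one_row_per_error(self):
        m = next(iter(random_instances(1, seed=21, max_inputs=1)))
        spec = MutantSpec(kind="gate_flip", errors_per_network=3,
                          ensemble_size=10)
        for mut in generate_mutant_ensemble(m, spec, rng=1):
            dist = 0
            for a, b in zip(m.nodes, mut.nodes):
                assert a.regulators == b.regulators
                dist += sum(x != y for x, y in
                            zip(a.truth_table, b.truth_table))
            assert dist == 3

    def test_node_lock_spares_inputs_and_locks_constant(self):
        m = next(iter(random_instances(1, seed=22, max_inputs=2)))
        spec = MutantSpec(kind="node_lock", errors_per_network=2,
                          ensemble_size=10)
        for mut in generate_mutant_ensemble(m, spec, rng=2):
            locked = [b for a, b in zip(m.nodes, mut.nodes)
                      if a.truth_table != b.truth_table]
            assert len(locked) <= 2
            for b in locked:
                assert b.regulators == () and len(b.truth_table) == 1
                assert not m.is_input(b.name)

    def test_link_removal_matches_direct_reduction(self):
        m = next(iter(random_instances(1, seed=25, max_inputs=1)))
        spec = MutantSpec(kind="link_removal", errors_per_network=4,
                          ensemble_size=10)
        for mut in generate_mutant_ensemble(m, spec, rng=3):
            for a, b in zip(m.nodes, mut.nodes):
                if a.regulators == b.regulators:
                    assert a.truth_table == b.truth_table
                    continue
                removed = [r for r in a.regulators if r not in b.regulators]
                expect = reduce_gate_frozen_inputs(a, removed)
                assert b.truth_table == expect.truth_table

    def test_too_many_errors_rejected(self, toggle):
        spec = MutantSpec(kind="link_removal", errors_per_network=99,
                          ensemble_size=1)
        with pytest.raises(ValueError, match="link"):
            next(generate_mutant_ensemble(toggle, spec, rng=0))

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            MutantSpec(kind="weird", errors_per_network=1, ensemble_size=1)
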