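"""Phenotype signatures, cell-cycle event detectors, dwell statistics."""

import numpy as np
import pytest

from mechbool.fixtures import marker_stub_model, scripted_trajectory
from mechbool.model import parse_model
from mechbool.perturbation import InputSchedule
from mechbool.phenotypes import (DEFAULT_EVENT_DETECTORS, EventDetector,
                                 PhenotypeSignature, classify_state,
                                 detect_cycle_events, load_default_signatures,
                                 load_signatures, run_phenotype_statistics)


class TestSignatures:
    def test_parse_published_hybrid_signature_line(self):
        text = ("Hybrid_EM = (*miR_34*=0, *miR_200*=1, *Ecadherin_mRNA*=1, "
                "*ZEB1_H*=0, *ZEB1*=1, *SNAI1*=1)")
        (sig,) = load_signatures(text)
        assert sig.name == "Hybrid_EM"
        assert ("miR_34", 0) in sig.constraints
        assert ("ZEB1", 1) in sig.constraints
        assert len(sig.constraints) == 6

    def test_packaged_defaults_cover_the_seven_phenotypes(self):
        names = {s.name for s in load_signatures(
            __import__("mechbool.phenotypes", fromlist=["x"]).DEFAULT_SIGNATURE_TEXT)}
        assert names == {"CIP", "noCIP", "Migratory", "Non-migratory",
                         "Epithelial", "Mesenchymal", "Hybrid_EM"}

    def test_empty_constraints_match_everything(self, emt_switch, rng):
        sig = PhenotypeSignature("anything", ())
        state = rng.integers(0, 2, emt_switch.n_nodes).astype(np.uint8)
        assert sig.matches(emt_switch, state)

    def test_unknown_node_raises_at_bind_time(self, toggle):
        sig = PhenotypeSignature("bad", (("Zeb999", 1),))
        with pytest.raises(ValueError, match="Zeb999"):
            sig.validate(toggle)

    def test_malformed_lines_rejected(self):
        with pytest.raises(ValueError, match="line 1"):
            load_signatures("Epithelial = miR_34=1")
        with pytest.raises(ValueError, match="0/1"):
            load_signatures("E = (miR_34=2)")

    def test_match_frequency_follows_constraint_count(self, rng):
        m = parse_model("\n".join(f"X{i} *= X{i} or X{i}" for i in range(8)))
        sig = PhenotypeSignature("s", (("X0", 1), ("X3", 0), ("X5", 1)))
        n = 20_000
        states = rng.integers(0, 2, (n, m.n_nodes)).astype(np.uint8)
        hits = sum(sig.matches(m, s) for s in states)
        p = 2.0 ** -3
        sigma = np.sqrt(n * p * (1 - p))
        assert abs(hits - n * p) < 3 * sigma

    def test_classification_returns_all_matching_names(self, emt_switch):
        sigs = load_default_signatures(emt_switch, strict=False)
        epi = {n: 0 for n in emt_switch.node_names}
        epi.update(NFkB=1, c_Myb=1, miR_34=1, miR_200=1, Ecadherin_mRNA=1)
        names = classify_state(emt_switch, emt_switch.make_state(epi), sigs)
        assert "Epithelial" in names and "Mesenchymal" not in names

    def test_hybrid_attractor_classified_hybrid(self, emt_switch):
        from mechbool.attractors import enumerate_attractors_exhaustive
        sigs = load_default_signatures(emt_switch, strict=False)
        labels = []
        for att in enumerate_attractors_exhaustive(emt_switch, {}):
            labels.append(classify_state(emt_switch, att.state_array(0), sigs))
        flat = [frozenset(l) for l in labels]
        assert any("Hybrid_EM" in l for l in flat)
        assert any("Epithelial" in l for l in flat)
        assert any("Mesenchymal" in l for l in flat)


def _tracks(model, T=30, **kw):
    d = {n: [0] * T for n in model.node_names}
    for node, steps in kw.items():
        for t in steps:
            d[node][t] = 1
    return d


@pytest.fixture(scope="module")
def stub():
    return marker_stub_model()


class TestEventDetectors:

    def test_quiescent_trajectory_counts_nothing(self, stub):
        traj = scripted_trajectory(stub, _tracks(stub))
        c = detect_cycle_events(stub, traj)
        assert c.event_counts() == {"normal_cycle": 0, "g2_reset": 0,
                                    "aberrant_mitosis": 0,
                                    "failed_cytokinesis": 0}

    @pytest.mark.parametrize("kw,expected", [
        # cytokinesis pulse with attached kinetochores after a CyclinB pulse
        (dict(CyclinB=range(5, 9), A_Kinetochores=range(10, 13),
              Cytokinesis=[11, 12]), "normal_cycle"),
        # 4N flag rises with no CyclinB pulse since the last cytokinesis
        (dict(f4N_DNA=range(5, 9)), "g2_reset"),
        # metaphase-anaphase transition without kinetochore attachment
        (dict(Cdc20=[7, 8]), "aberrant_mitosis"),
        # orderly mitotic exit then a new replication round with no
        # cytokinesis in between
        (dict(A_Kinetochores=[4, 5, 6], Cdc20=[5, 6], Replication=[15, 16]),
         "failed_cytokinesis"),
    ])
    def test_each_scripted_event_fires_its_own_counter(self, stub, kw, expected):
        traj = scripted_trajectory(stub, _tracks(stub, **kw))
        counts = detect_cycle_events(stub, traj).event_counts()
        assert counts[expected] == 1
        assert sum(counts.values()) == 1

    def test_cytokinesis_after_mitosis_suppresses_failed_cytokinesis(self, stub):
        kw = dict(CyclinB=range(3, 7), A_Kinetochores=range(7, 11),
                  Cdc20=[8, 9], Cytokinesis=[10, 11], Replication=[20, 21])
        traj = scripted_trajectory(stub, _tracks(stub, **kw))
        counts = detect_cycle_events(stub, traj).event_counts()
        assert counts["failed_cytokinesis"] == 0
        assert counts["normal_cycle"] == 1

    def test_repeated_cycles_count_each_pulse(self, stub):
        kw = dict(CyclinB=[3, 4, 13, 14], A_Kinetochores=[5, 6, 15, 16],
                  Cytokinesis=[5, 6, 15, 16])
        traj = scripted_trajectory(stub, _tracks(stub, **kw))
        assert detect_cycle_events(stub, traj).normal_cycles == 2

    def test_missing_node_rejected(self, toggle):
        det = EventDetector("x", trigger=("CyclinB", "rise"))
        with pytest.raises(ValueError, match="missing node"):
            detect_cycle_events(toggle, np.zeros((3, 2), np.uint8), (det,))


class TestStatistics:
    def test_dwell_matches_two_state_markov_chain(self):
        # node X follows a stochastic input directly: dwell fraction of
        # X=1 equals the input ON-probability (closed-form stationary law)
        m = parse_model("GF *= GF\nX *= GF\n")
        sigs = [PhenotypeSignature("Xon", (("X", 1),))]
        p = 0.3
        stats = run_phenotype_statistics(
            m, m.make_state({"GF": 0, "X": 0}), InputSchedule({"GF": p}),
            sigs, t_min_live=20_000, rng=1)
        n = stats.counters.live_steps
        sigma = np.sqrt(p * (1 - p) / n)
        assert abs(stats.dwell_fractions["Xon"] - p) < 4 * sigma

    def test_apoptosis_restarts_accumulate_live_time(self):
        # Apoptosis fires whenever the stochastic input goes ON
        m = parse_model("Death *= Death\nApoptosis *= Death\nX *= X or Apoptosis\n")
        sigs = [PhenotypeSignature("Xoff", (("X", 0),))]
        stats = run_phenotype_statistics(
            m, m.make_state({"Death": 0, "Apoptosis": 0, "X": 0}),
            InputSchedule({"Death": 0.05}), sigs, t_min_live=2000, rng=2)
        assert stats.counters.live_steps >= 2000
        assert stats.counters.apoptoses > 0
        assert stats.restarts == stats.counters.apoptoses + 1 or \
            stats.restarts == stats.counters.apoptoses

    def test_always_lethal_environment_flagged_degenerate(self):
        m = parse_model("Death *= Death\nApoptosis *= Death\n")
        sigs = [PhenotypeSignature("any", ())]
        stats = run_phenotype_statistics(
            m, m.make_state({"Death": 1, "Apoptosis": 0}),
            InputSchedule({"Death": 1}), sigs, t_min_live=1000,
            max_restarts=50, rng=0)
        assert stats.degenerate
        assert np.isnan(stats.dwell_fractions["any"])

    def test_exclusive_phenotypes_dwell_sums_below_one(self, emt_switch):
        sigs = load_default_signatures(emt_switch, strict=False)
        stats = run_phenotype_statistics(
            emt_switch, np.zeros(emt_switch.n_nodes, np.uint8),
            InputSchedule({}), sigs, engine="noisy", p_noise=0.05,
            t_min_live=3000, rng=3)
        trio = sum(stats.dwell_fractions[k]
                   for k in ("Epithelial", "Hybrid_EM", "Mesenchymal"))
        assert 0.0 < trio <= 1.0
        for k, v in stats.dwell_fractions.items():
            assert 0.0 <= v <= 1.0

    def test_event_rates_stable_under_doubled_run_length(self):
        m = marker_stub_model()
        # drive a deterministic 10-step cycle through the markers via noise-free
        # stochastic schedule: use probabilistic inputs to generate pulses
        sched = InputSchedule({"CyclinB": 0.5, "Cdc20": 0.0,
                               "A_Kinetochores": 1.0, "Cytokinesis": 0.5,
                               "Replication": 0.0, "f4N_DNA": 0.0,
                               "Apoptosis": 0.0})
        sigs = [PhenotypeSignature("any", ())]
        r = []
        for t_min in (4000, 8000):
            stats = run_phenotype_statistics(
                m, np.zeros(m.n_nodes, np.uint8), sched, sigs,
                t_min_live=t_min, rng=9)
            r.append(stats.event_rates["normal_cycle"])
        assert r[0] > 0
        assert abs(r[0] - r[1]) / r[0] < 0.25
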