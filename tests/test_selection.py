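"""Greedy set assembly against an independently coded step-by-step oracle."""

import numpy as np
import pandas as pd
import pytest

from kinoset import (
    ActivityMatrix,
    AssayPanel,
    Candidate,
    InclusionDecision,
    KdRecord,
    KinaseAssay,
    KinosetError,
    SelectionConfig,
    filter_candidates,
    greedy_assemble,
)


def cand(cid, kinases, s10=0.01):
    return Candidate(
        compound=cid,
        s10=s10,
        qualifying_kinases=frozenset(kinases),
        decision=InclusionDecision(cid, True, sorted(kinases), s10),
    )


def oracle_greedy(candidates, bin_of, depth_target=2, weights=None):
    """Independent re-implementation: explicit loops, no shared code paths."""
    weights = weights or {}
    chosen = []
    kinase_bins = {}
    exemplars = {}
    pool = list(candidates)
    while pool:
        best = None
        for c in pool:
            g = 0.0
            for k in sorted(c.qualifying_kinases):
                have = kinase_bins.get(k, set())
                if len(have) < depth_target and bin_of[c.compound] not in have:
                    g += weights.get(k, 1.0)
            key = (
                -g,
                exemplars.get(bin_of[c.compound], 0),
                c.s10,
                c.compound,
            )
            if best is None or key < best[0]:
                best = (key, c, g)
        _, pick, g = best
        if g <= 0:
            break
        chosen.append(pick.compound)
        exemplars[bin_of[pick.compound]] = exemplars.get(bin_of[pick.compound], 0) + 1
        for k in pick.qualifying_kinases:
            kinase_bins.setdefault(k, set()).add(bin_of[pick.compound])
        pool = [c for c in pool if c.compound != pick.compound]
    return chosen


class TestFilterCandidates:
    def test_mixed_failures(self, small_matrix):
        kd = [
            KdRecord("SEL1", "AURKC", 50.0),     # potent, selective -> passes
            KdRecord("PROM1", "AURKC", 20.0),    # potent but S10 = 1 -> fails
            # INACT1 has no K_D -> fails
        ]
        config = SelectionConfig(s10_max=0.4)
        out = filter_candidates(small_matrix, kd, config)
        assert [c.compound for c in out] == ["SEL1"]
        assert out[0].qualifying_kinases == frozenset({"AURKC"})

    def test_empty_kd_table_no_candidates(self, small_matrix):
        assert filter_candidates(small_matrix, []) == []

    def test_planted_passers_recovered_exactly(self):
        from kinoset import FixtureSpec, gen_profiles

        spec = FixtureSpec(seed=7, n_compounds=100, kd_fail_fraction=0.3)
        matrix, kd, truth = gen_profiles(spec)
        out = filter_candidates(matrix, kd)
        got = {c.compound for c in out}
        expected = set(truth[truth.expected_pass].compound)
        assert got == expected
        assert len(expected) > 0  # fixture actually plants passers


class TestGreedyAssemble:
    def test_same_bin_duplicate_adds_nothing(self):
        cands = [cand("A", {"K"}), cand("B", {"K"})]
        bins = {"A": "X", "B": "X"}
        s = greedy_assemble(cands, bins, SelectionConfig(depth_target=2))
        assert s.compounds == ["A"]  # B's bin is not new for K -> gain 0

    def test_two_chemotypes_preferred_over_redundant_one(self):
        cands = [cand("A", {"K"}, s10=0.004), cand("B", {"K"}, s10=0.008),
                 cand("C", {"K"}, s10=0.02)]
        bins = {"A": "X", "B": "X", "C": "Y"}
        s = greedy_assemble(cands, bins, SelectionConfig(depth_target=2))
        # A vs B tie on gain and exemplars -> lower S10 wins; then C's new
        # chemotype still gains; never both A and B
        assert s.compounds == ["A", "C"]
        assert s.depth_table()["K"] == (2, 2)

    def test_missing_bin_assignment_errors(self):
        with pytest.raises(KinosetError, match="without chemotype"):
            greedy_assemble([cand("A", {"K"})], {}, SelectionConfig())

    def test_sole_coverer_always_selected(self, rng):
        """A kinase coverable by exactly one candidate gets that candidate."""
        for trial in range(20):
            n_c, n_k = 6, 5
            kin = [f"K{i}" for i in range(n_k)]
            cands = []
            for i in range(n_c):
                ks = set(np.array(kin)[rng.random(n_k) < 0.4])
                cands.append(cand(f"C{i}", ks, s10=float(rng.uniform(0, 0.02))))
            # plant a kinase only candidate C0 covers
            cands[0] = cand("C0", set(cands[0].qualifying_kinases) | {"UNIQ"},
                            s10=cands[0].s10)
            bins = {f"C{i}": f"B{rng.integers(0, 3)}" for i in range(n_c)}
            s = greedy_assemble(cands, bins, SelectionConfig())
            assert "C0" in s.compounds

    def test_coverage_strictly_increases_each_step(self, rng):
        kin = [f"K{i}" for i in range(8)]
        cands = [
            cand(f"C{i}", set(np.array(kin)[rng.random(8) < 0.5]),
                 s10=float(rng.uniform(0, 0.02)))
            for i in range(10)
        ]
        cands = [c for c in cands if c.qualifying_kinases]
        bins = {c.compound: f"B{rng.integers(0, 4)}" for c in cands}
        config = SelectionConfig(depth_target=2)
        s = greedy_assemble(cands, bins, config)

        def objective(selected):
            kb = {}
            for cid in selected:
                c = next(x for x in cands if x.compound == cid)
                for k in c.qualifying_kinases:
                    kb.setdefault(k, set()).add(bins[cid])
            return sum(min(2, len(v)) for v in kb.values())

        vals = [objective(s.compounds[:i]) for i in range(len(s.compounds) + 1)]
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_audit_log_replays_selection(self, rng):
        cands = [
            cand(f"C{i}", {f"K{j}" for j in rng.choice(6, 3, replace=False)},
                 s10=float(rng.uniform(0, 0.02)))
            for i in range(8)
        ]
        bins = {c.compound: f"B{rng.integers(0, 3)}" for c in cands}
        s = greedy_assemble(cands, bins, SelectionConfig())
        assert [st.picked for st in s.audit] == s.compounds
        assert all(st.gain > 0 for st in s.audit)

    def test_equals_oracle_on_random_small_instances(self, rng):
        """Exhaustive-style check across many <=8 candidates x <=6 kinases."""
        for trial in range(300):
            n_c = int(rng.integers(1, 9))
            n_k = int(rng.integers(1, 7))
            kin = [f"K{i}" for i in range(n_k)]
            cands = []
            for i in range(n_c):
                ks = {k for k in kin if rng.random() < 0.5}
                # quantized s10 values force frequent exact ties
                s10 = float(rng.integers(0, 4)) / 200.0
                cands.append(cand(f"C{i}", ks, s10=s10))
            bins = {f"C{i}": f"B{rng.integers(0, 3)}" for i in range(n_c)}
            depth = int(rng.integers(1, 4))
            weights = None
            if rng.random() < 0.3:
                weights = {k: float(rng.integers(1, 5)) / 4.0 for k in kin}
            config = SelectionConfig(depth_target=depth,
                                     publication_weights=weights)
            got = greedy_assemble(cands, bins, config).compounds
            want = oracle_greedy(cands, bins, depth_target=depth,
                                 weights=weights)
            assert got == want, f"trial {trial}"

    def test_publication_weights_divert_selection(self):
        # two candidates, same bin-free gain structure; down-weighting the
        # famous kinase makes the dark-kinase coverer win the first step
        cands = [cand("FAMOUS", {"EGFR"}, s10=0.001),
                 cand("DARK", {"DKFZ1"}, s10=0.01)]
        bins = {"FAMOUS": "X", "DARK": "Y"}
        config = SelectionConfig(publication_weights={"EGFR": 0.2})
        s = greedy_assemble(cands, bins, config)
        assert s.compounds[0] == "DARK"
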