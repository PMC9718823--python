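"""TRAP affinity model, rank tests, and BH adjustment."""

import itertools

import numpy as np
import pandas as pd
import pytest

from chromlink.motifs import (PWM, bh_adjust, default_ln_r0,
                              enrichment_analysis, filter_expressed_tfs,
                              mann_whitney_one_tailed, read_jaspar,
                              reverse_complement, trap_affinity, write_jaspar)


@pytest.fixture
def uniform_pwm():
    return PWM("uniform", np.full((6, 4), 0.25))


@pytest.fixture
def sharp_pwm():
    """Near-consensus matrix for ACGTAC."""
    counts = np.full((6, 4), 1.0)
    for i, b in enumerate("ACGTAC"):
        counts[i, "ACGT".index(b)] = 97.0
    return PWM.from_counts("sharp", counts, pseudocount=0)


class TestTrapAffinity:
    def test_uniform_pwm_closed_form(self, uniform_pwm):
        """Every window has zero energy: affinity = 2 (L-W+1) R0/(1+R0)."""
        L, W = 50, uniform_pwm.width
        r0 = np.exp(default_ln_r0(W))
        expected = 2 * (L - W + 1) * r0 / (1 + r0)
        seq = "".join(np.random.default_rng(0).choice(list("ACGT"), L))
        assert trap_affinity(uniform_pwm, seq) == pytest.approx(expected)

    def test_matches_direct_per_window_oracle(self, sharp_pwm):
        rng = np.random.default_rng(1)
        seq = "".join(rng.choice(list("ACGT"), 40))
        lam, ln_r0 = 0.7, default_ln_r0(sharp_pwm.width)
        probs = sharp_pwm.probabilities
        idx = {b: i for i, b in enumerate("ACGT")}

        def site_prob(window, mat):
            e = sum(
                np.log(mat[j].max() / mat[j, idx[b]])
                for j, b in enumerate(window)
            ) / lam
            return np.exp(ln_r0 - e) / (1 + np.exp(ln_r0 - e))

        w = sharp_pwm.width
        rc_probs = probs[::-1, [3, 2, 1, 0]]
        oracle = sum(
            site_prob(seq[i:i + w], probs) + site_prob(seq[i:i + w], rc_probs)
            for i in range(len(seq) - w + 1)
        )
        assert trap_affinity(sharp_pwm, seq) == pytest.approx(oracle)

    def test_consensus_match_adds_one_site_probability(self, sharp_pwm):
        """A perfect site adds ~R0/(1+R0) (the zero-energy occupancy)."""
        rng = np.random.default_rng(2)
        background = "".join(rng.choice(list("TTGG"), 60))
        seeded = background[:20] + "ACGTAC" + background[26:]
        r0 = np.exp(default_ln_r0(sharp_pwm.width))
        gain = trap_affinity(sharp_pwm, seeded) - \
            trap_affinity(sharp_pwm, background)
        assert gain == pytest.approx(r0 / (1 + r0), rel=0.1)
        assert gain > 0.05

    def test_reverse_complement_symmetry(self, sharp_pwm, uniform_pwm):
        rng = np.random.default_rng(3)
        for pwm in (sharp_pwm, uniform_pwm):
            seq = "".join(rng.choice(list("ACGT"), 33))
            assert trap_affinity(pwm, seq) == pytest.approx(
                trap_affinity(pwm, reverse_complement(seq))
            )

    def test_additive_over_concatenation_up_to_boundary(self, sharp_pwm):
        rng = np.random.default_rng(4)
        s1 = "".join(rng.choice(list("ACGT"), 30))
        s2 = "".join(rng.choice(list("ACGT"), 30))
        whole = trap_affinity(sharp_pwm, s1 + s2)
        parts = trap_affinity(sharp_pwm, s1) + trap_affinity(sharp_pwm, s2)
        # difference only from the W-1 junction windows, each with P <= 1
        assert abs(whole - parts) <= 2 * (sharp_pwm.width - 1)
        assert whole >= parts - 1e-9

    def test_n_windows_contribute_zero(self, uniform_pwm):
        r0 = np.exp(default_ln_r0(uniform_pwm.width))
        per_window = 2 * r0 / (1 + r0)
        # one N kills exactly W overlapping windows per strand
        clean = trap_affinity(uniform_pwm, "A" * 20)
        with_n = trap_affinity(uniform_pwm, "A" * 10 + "N" + "A" * 9)
        assert clean - with_n == pytest.approx(
            uniform_pwm.width * per_window
        )

    def test_too_short_sequence_warns_and_zero(self, sharp_pwm):
        with pytest.warns(UserWarning, match="shorter"):
            assert trap_affinity(sharp_pwm, "ACG") == 0.0


class TestPwmIO:
    def test_jaspar_round_trip(self, tmp_path):
        counts = np.array(
            [[10, 0, 0, 2], [0, 8, 2, 2], [1, 1, 9, 1]], dtype=float
        )
        path = tmp_path / "m.jaspar"
        write_jaspar(["TF_X"], [counts], path)
        pwms = read_jaspar(path, pseudocount=1.0)
        assert pwms[0].tf_name == "TF_X"
        expected = (counts + 1) / (counts + 1).sum(axis=1, keepdims=True)
        assert np.allclose(pwms[0].probabilities, expected)

    def test_pwm_validation(self):
        with pytest.raises(ValueError, match="pseudocount"):
            PWM("bad", np.array([[1.0, 0.0, 0.0, 0.0]]))


class TestExpressedFilter:
    def test_inclusive_threshold_and_warnings(self):
        expr = pd.DataFrame(
            {"gene_id": ["ga", "gb"], "rpkm_ctrl": [1.0, 0.3],
             "rpkm_ko": [0.2, 0.9]}
        )
        pwms = [PWM(n, np.full((4, 4), 0.25)) for n in ("t1", "t2", "t3")]
        mapping = {"t1": "ga", "t2": "gb"}
        with pytest.warns(UserWarning, match="no expression record"):
            kept = filter_expressed_tfs(pwms, expr, mapping)
        assert [p.tf_name for p in kept] == ["t1"]


def mw_enumeration_oracle(a, b):
    """Exact one-tailed p by enumerating all label assignments."""
    pooled = np.concatenate([a, b])
    na = len(a)

    def u(av, bv):
        return sum(
            (x > y) + 0.5 * (x == y) for x in av for y in bv
        )

    u_obs = u(a, b)
    us = [
        u(pooled[list(c)], np.delete(pooled, list(c)))
        for c in itertools.combinations(range(len(pooled)), na)
    ]
    return u_obs, float(np.mean([v >= u_obs - 1e-12 for v in us]))


class TestMannWhitney:
    def test_spec_example_maximal_u(self):
        u, p = mann_whitney_one_tailed([3, 4], [1, 2])
        assert u == 4 and p == pytest.approx(1 / 6)

    def test_identical_multisets_not_significant(self):
        _, p = mann_whitney_one_tailed([1, 2, 3], [1, 2, 3])
        assert p >= 0.5

    def test_reversed_direction_complementary(self):
        _, p = mann_whitney_one_tailed([1, 2], [3, 4])
        assert p == pytest.approx(1.0)

    def test_exact_matches_enumeration_no_ties(self):
        rng = np.random.default_rng(6)
        for na in range(1, 6):
            for nb in range(1, 6):
                vals = rng.choice(100, na + nb, replace=False).astype(float)
                a, b = vals[:na], vals[na:]
                u, p = mann_whitney_one_tailed(a, b)
                uo, po = mw_enumeration_oracle(a, b)
                assert u == pytest.approx(uo)
                assert p == pytest.approx(po, abs=1e-12)

    def test_tied_u_uses_midranks(self):
        rng = np.random.default_rng(7)
        for _ in range(40):
            a = rng.integers(1, 5, rng.integers(2, 6)).astype(float)
            b = rng.integers(1, 5, rng.integers(2, 6)).astype(float)
            u, _ = mann_whitney_one_tailed(a, b)
            uo, _ = mw_enumeration_oracle(a, b)
            assert u == pytest.approx(uo)

    def test_all_identical_p_one(self):
        u, p = mann_whitney_one_tailed([2.0, 2.0], [2.0, 2.0, 2.0])
        assert p == 1.0


class TestBh:
    def test_step_up_arithmetic(self):
        adj = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged_and_boundary_significant(self):
        adj = bh_adjust([0.05])
        assert adj[0] == pytest.approx(0.05)
        assert adj[0] <= 0.05

    def test_monotone_and_above_raw(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(0.001, 1, 30)
        adj = bh_adjust(p)
        assert np.all(adj >= p - 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)


class TestEnrichment:
    def test_planted_motif_detected_in_group_b(self):
        rng = np.random.default_rng(10)
        motif = "TGACGTCA"
        counts = np.full((8, 4), 5.0)
        for i, b in enumerate(motif):
            counts[i, "ACGT".index(b)] = 85.0
        planted = PWM.from_counts("planted", counts)
        decoy = PWM("decoy", np.full((8, 4), 0.25))

        def rand_seq(n):
            return "".join(rng.choice(list("ACGT"), n))

        group_a = {f"a{i}": rand_seq(300) for i in range(12)}
        group_b = {}
        for i in range(12):
            s = list(rand_seq(300))
            for pos in (20, 80, 140, 200, 260):
                s[pos:pos + 8] = list(motif)
            group_b[f"b{i}"] = "".join(s)
        table = enrichment_analysis([planted, decoy], group_a, group_b)
        top = table.iloc[0]
        assert top["tf_name"] == "planted"
        assert top["direction"] == "B"
        assert top["significant"]

    def test_no_planted_sites_rarely_yields_any_significant_tf(self):
        """With zero planted motif sites the activating/silencing RE groups
        are exchangeable, so a significant TF should appear in well under
        10% of seeds (measured over 60 seeds for resolution)."""
        import warnings
        from chromlink.simulate import (TruthConfig, generate_genome,
                                        generate_re_sequences, plant_truth)

        clean = 0
        n_seeds = 60
        for seed in range(n_seeds):
            cfg = TruthConfig(
                seed=seed, n_genes=150,
                chrom_sizes={"chr1": 6_000_000, "chr2": 6_000_000,
                             "chrX": 2_000_000},
                n_sites_per_silencing_re=0,
            )
            genes, _ = generate_genome(cfg)
            _, re_truth = plant_truth(cfg, genes)
            seqs, names, counts = generate_re_sequences(cfg, re_truth)
            pwms = [PWM.from_counts(n, c) for n, c in zip(names, counts)]
            act = {r: seqs[r] for r in re_truth.loc[
                re_truth["re_type"] == "activating", "re_id"]}
            sil = {r: seqs[r] for r in re_truth.loc[
                re_truth["re_type"] == "silencing", "re_id"]}
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                table = enrichment_analysis(pwms, act, sil)
            clean += not table["significant"].any()
        assert clean / n_seeds > 0.9
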