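import numpy as np
import pandas as pd
import pytest

from conftest import make_genotype_matrix
from polyport import prs_engine as pe
from polyport import synthetic_data as sd


def make_sumstats(ids, positions, pvals, betas=None, chromosome="1",
                  effect="G", other="A"):
    n = len(ids)
    return pd.DataFrame(
        {
            "variant_id": ids,
            "chromosome": str(chromosome),
            "position": positions,
            "effect_allele": [effect] * n if isinstance(effect, str) else list(effect),
            "other_allele": [other] * n if isinstance(other, str) else list(other),
            "beta": betas if betas is not None else np.ones(n),
            "se": 0.1,
            "p": pvals,
        }
    )


# ---------------------------------------------------------------- harmonize

class TestHarmonize:
    def _target(self):
        return make_genotype_matrix(np.array([[0.0, 1.0], [1.0, 2.0], [2.0, 0.0]]),
                                    ids=["rs1", "rs2"], ref=["A", "C"], alt=["G", "T"])

    def test_effect_allele_alt_keeps_sign(self):
        ss = make_sumstats(["rs1"], [1000], [0.01], betas=[0.5], effect="G", other="A")
        hw = pe.harmonize(ss, self._target())
        assert hw.table.loc[0, "weight"] == 0.5
        assert hw.table.loc[0, "action"] == "match"

    def test_effect_allele_ref_flips_sign(self):
        ss = make_sumstats(["rs1"], [1000], [0.01], betas=[0.5], effect="A", other="G")
        hw = pe.harmonize(ss, self._target())
        assert hw.table.loc[0, "weight"] == -0.5
        assert hw.table.loc[0, "action"] == "sign_flip"

    def test_ambiguous_policy(self):
        target = make_genotype_matrix(np.ones((3, 1)), ids=["rs1"], ref="A", alt="T")
        ss = make_sumstats(["rs1"], [1000], [0.01], betas=[0.5], effect="T", other="A")
        dropped = pe.harmonize(ss, target, drop_ambiguous=True)
        kept = pe.harmonize(ss, target, drop_ambiguous=False)
        assert dropped.counts["dropped_ambiguous"] == 1 and len(dropped.table) == 0
        assert kept.table.loc[0, "action"] == "match"

    def test_mismatch_and_absent_recorded(self):
        ss = make_sumstats(["rs1", "rs9"], [1000, 9000], [0.01, 0.01],
                           effect=["C", "G"], other=["A", "A"])
        hw = pe.harmonize(ss, self._target())
        assert hw.counts["dropped_mismatch"] == 1
        assert hw.counts["dropped_absent"] == 1
        assert len(hw.audit) == 2  # every source row has a recorded action

    def test_counts_cover_all_rows(self):
        ss = make_sumstats(["rs1", "rs2", "rs9"], [1000, 2000, 9000], [0.1, 0.2, 0.3],
                           effect=["G", "T", "A"], other=["A", "C", "G"])
        hw = pe.harmonize(ss, self._target())
        assert sum(hw.counts.values()) == len(ss)


# ---------------------------------------------------------------- ld_r2

class TestLdR2:
    def test_self_correlation_is_one(self):
        gm = make_genotype_matrix(np.array([[0.0], [1.0], [2.0], [1.0]]))
        assert pe.ld_r2(gm, 0, 0) == pytest.approx(1.0)

    def test_hand_computed_value(self):
        # g1=(0,1,2,2), g2=(0,1,1,2): Pearson r^2 = 8/11 (hand computation)
        gm = make_genotype_matrix(np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 1.0], [2.0, 2.0]]))
        assert pe.ld_r2(gm, 0, 1) == pytest.approx(8 / 11)

    def test_independent_variants_near_zero(self):
        pf = pd.DataFrame([np.full(20, 0.5)], index=["P"])
        gm, _ = sd.simulate_genotypes(pf, 2000, block_size=1, within_block_r=0.0, seed=31)
        vals = [pe.ld_r2(gm, i, j) for i in range(10) for j in range(10, 20)]
        assert np.mean(vals) < 0.01

    def test_monomorphic_raises(self):
        gm = make_genotype_matrix(np.array([[1.0, 0.0], [1.0, 1.0], [1.0, 2.0]]))
        with pytest.raises(pe.UndefinedLDError):
            pe.ld_r2(gm, 0, 1)

    def test_pairwise_complete_only(self):
        d = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 1.0], [2.0, 2.0], [np.nan, 2.0]])
        gm = make_genotype_matrix(d)
        assert pe.ld_r2(gm, 0, 1) == pytest.approx(8 / 11)


# ---------------------------------------------------------------- clump

def brute_force_clump(sumstats, reference, spec):
    """Literal restatement of the greedy clumping rules (independent oracle)."""
    ref_keys = list(reference.join_keys())
    rows = []
    for _, row in sumstats.iterrows():
        key = row["variant_id"]
        if key not in ref_keys:
            continue
        rows.append(dict(row, ref_col=ref_keys.index(key)))
    assigned = set()
    indices = []
    ordered = sorted(rows, key=lambda r: (r["p"], r["chromosome"], r["position"], r["variant_id"]))
    for row in ordered:
        if row["variant_id"] in assigned or row["p"] > spec.p1:
            continue
        assigned.add(row["variant_id"])
        indices.append(row["variant_id"])
        gi = reference.dosages[:, row["ref_col"]]
        for other in ordered:
            if other["variant_id"] in assigned:
                continue
            if other["chromosome"] != row["chromosome"]:
                continue
            if abs(other["position"] - row["position"]) > spec.window_kb * 1000:
                continue
            if other["p"] > spec.p2:
                continue
            gj = reference.dosages[:, other["ref_col"]]
            if gi.var() == 0 or gj.var() == 0:
                continue
            r2 = np.corrcoef(gi, gj)[0, 1] ** 2
            if r2 >= spec.r2_threshold:
                assigned.add(other["variant_id"])
    return sorted(indices)


class TestClump:
    def _toy(self):
        # exact r^2 by construction: r2(A,B) = 0.5, r2(A,C) = 0
        dosages = np.array(
            [[0.0, 0.0, 0.0], [0.0, 1.0, 1.0], [1.0, 1.0, 0.0], [1.0, 2.0, 1.0]]
        )
        ref = make_genotype_matrix(dosages, positions=[100_000, 150_000, 2_000_000],
                                   ids=["A", "B", "C"])
        ss = make_sumstats(["A", "B", "C"], [100_000, 150_000, 2_000_000],
                           [1e-8, 1e-6, 1e-4])
        return ss, ref

    def test_single_variant_is_sole_index(self):
        gm = make_genotype_matrix(np.array([[0.0], [1.0], [2.0], [1.0]]), ids=["A"])
        ss = make_sumstats(["A"], [1000], [0.5])
        clumped, assignment = pe.clump(ss, gm, pe.ClumpSpec())
        assert list(clumped["variant_id"]) == ["A"]
        assert assignment == {"A": []}

    def test_toy_three_variants_threshold_point_two(self):
        ss, ref = self._toy()
        clumped, assignment = pe.clump(ss, ref, pe.ClumpSpec(r2_threshold=0.2))
        assert sorted(clumped["variant_id"]) == ["A", "C"]
        assert assignment["A"] == ["B"]

    def test_toy_three_variants_threshold_point_six(self):
        ss, ref = self._toy()
        clumped, _ = pe.clump(ss, ref, pe.ClumpSpec(r2_threshold=0.6))
        assert sorted(clumped["variant_id"]) == ["A", "B", "C"]

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(32)
        for trial in range(60):
            m = int(rng.integers(1, 51))
            n = 40
            freqs = rng.uniform(0.1, 0.9, m)
            base = rng.binomial(2, freqs, size=(n, m)).astype(float)
            # create LD by copying some columns with flip noise
            for j in range(1, m):
                if rng.random() < 0.4:
                    src = int(rng.integers(0, j))
                    noise = rng.random(n) < 0.15
                    base[:, j] = np.where(noise, rng.binomial(2, 0.5, n), base[:, src])
            positions = np.sort(rng.integers(1, 1_500_000, m))
            chroms = rng.choice(["1", "2"], m)
            ids = [f"v{j}" for j in range(m)]
            variants_gm = make_genotype_matrix(base, positions=list(positions), ids=ids)
            variants_gm.variants["chromosome"] = chroms
            pvals = rng.choice([1e-8, 1e-5, 1e-3, 0.05, 0.4, 0.9], m)  # deliberate ties
            ss = make_sumstats(ids, list(positions), pvals)
            ss["chromosome"] = chroms
            spec = pe.ClumpSpec(
                window_kb=int(rng.choice([50, 250, 500])),
                # non-round thresholds: exact rational r^2 values from integer
                # dosages must not land on the threshold boundary, where the
                # oracle and the implementation could round to opposite sides
                r2_threshold=float(rng.choice([0.1234567, 0.3141593, 0.5234567, 0.7854321])),
                p1=float(rng.choice([1.0, 0.1])),
                p2=float(rng.choice([1.0, 0.5])),
            )
            try:
                clumped, _ = pe.clump(ss, variants_gm, spec)
            except ValueError:
                assert not (ss["p"] <= spec.p1).any()
                continue
            assert sorted(clumped["variant_id"]) == brute_force_clump(ss, variants_gm, spec), (
                f"trial {trial} diverged from brute force"
            )

    def test_index_variants_pairwise_unlinked(self, three_pop_cohort):
        gm, _, _, sumstats, _ = three_pop_cohort
        ss = sumstats.iloc[:200]
        spec = pe.ClumpSpec(r2_threshold=0.2, window_kb=500)
        clumped, _ = pe.clump(ss, gm, spec)
        cols = {v: i for i, v in enumerate(gm.variants["variant_id"])}
        rows = clumped.to_dict("records")
        for i, a in enumerate(rows):
            for b in rows[i + 1:]:
                if a["chromosome"] != b["chromosome"]:
                    continue
                if abs(a["position"] - b["position"]) > spec.window_kb * 1000:
                    continue
                r2 = np.corrcoef(
                    gm.dosages[:, cols[a["variant_id"]]], gm.dosages[:, cols[b["variant_id"]]]
                )[0, 1] ** 2
                assert r2 < spec.r2_threshold

    def test_absent_from_reference_dropped_and_counted(self):
        gm = make_genotype_matrix(np.array([[0.0], [1.0], [2.0], [1.0]]), ids=["A"])
        ss = make_sumstats(["A", "Z"], [1000, 2000], [0.5, 0.1])
        clumped, _ = pe.clump(ss, gm, pe.ClumpSpec())
        assert list(clumped["variant_id"]) == ["A"]
        assert clumped.attrs["n_dropped_absent_from_reference"] == 1

    def test_empty_after_matching_raises(self):
        gm = make_genotype_matrix(np.array([[0.0], [1.0], [2.0], [1.0]]), ids=["A"])
        ss = make_sumstats(["Z"], [2000], [0.1])
        with pytest.raises(ValueError):
            pe.clump(ss, gm, pe.ClumpSpec())


# ---------------------------------------------------------------- threshold

class TestThreshold:
    def _weights(self, pvals):
        table = pd.DataFrame(
            {
                "variant_id": [f"rs{i}" for i in range(len(pvals))],
                "col": np.arange(len(pvals)),
                "weight": 1.0,
                "p": pvals,
                "action": "match",
            }
        )
        return pe.HarmonizedWeights(table=table, audit=table)

    def test_p_t_one_is_identity(self):
        hw = self._weights([0.001, 0.5, 1.0])
        assert len(pe.threshold(hw, 1.0)) == 3

    def test_strict_inequality_below_one(self):
        hw = self._weights([1e-9, 1e-7, 5e-8])
        sub = pe.threshold(hw, 5e-8)
        assert list(sub.table["variant_id"]) == ["rs0"]

    def test_nested_thresholds_give_nested_sets(self):
        rng = np.random.default_rng(33)
        hw = self._weights(rng.uniform(size=50))
        previous = set()
        for p_t in pe.DEFAULT_THRESHOLDS:
            current = set(pe.threshold(hw, p_t).table["variant_id"])
            assert previous <= current
            previous = current


# ---------------------------------------------------------------- score

class TestScore:
    def _weights(self, cols, weights, pvals=None):
        table = pd.DataFrame(
            {
                "variant_id": [f"rs{c}" for c in cols],
                "col": cols,
                "weight": weights,
                "p": pvals if pvals is not None else 0.5,
                "action": "match",
            }
        )
        return pe.HarmonizedWeights(table=table, audit=table)

    def test_single_variant_sum_and_average(self):
        gm = make_genotype_matrix(np.array([[2.0]]))
        hw = self._weights([0], [0.5])
        assert pe.score(gm, hw, mode="sum")[0] == pytest.approx(1.0)
        # average = sum / (2 * number of weighted variants) = 1.0 / 2
        assert pe.score(gm, hw, mode="average")[0] == pytest.approx(0.5)

    def test_all_zero_weights(self):
        gm = make_genotype_matrix(np.array([[2.0, 1.0], [0.0, 1.0]]))
        hw = self._weights([0, 1], [0.0, 0.0])
        assert (pe.score(gm, hw) == 0).all()

    def test_hand_sum_two_variants(self):
        gm = make_genotype_matrix(np.array([[2.0, 1.0]]))
        hw = self._weights([0, 1], [0.5, -1.0])
        assert pe.score(gm, hw)[0] == pytest.approx(0.0)

    def test_missing_dosage_mean_policy(self):
        gm = make_genotype_matrix(np.array([[2.0], [0.0], [np.nan]]))
        hw = self._weights([0], [1.0])
        s = pe.score(gm, hw, missing_policy="mean")
        assert s[2] == pytest.approx(1.0)  # cohort mean dosage of (2, 0)
        s0 = pe.score(gm, hw, missing_policy="zero")
        assert s0[2] == 0.0

    def test_additive_over_weight_partition(self):
        rng = np.random.default_rng(34)
        gm = make_genotype_matrix(rng.binomial(2, 0.5, size=(20, 10)).astype(float))
        weights = rng.normal(size=10)
        full = pe.score(gm, self._weights(list(range(10)), weights))
        part = pe.score(gm, self._weights(list(range(4)), weights[:4])) + pe.score(
            gm, self._weights(list(range(4, 10)), weights[4:])
        )
        np.testing.assert_allclose(full, part)

    def test_empty_weights_rejected(self):
        gm = make_genotype_matrix(np.array([[1.0]]))
        with pytest.raises(ValueError):
            pe.score(gm, self._weights([], []))


# ---------------------------------------------------------------- grid

class TestScoreGrid:
    def test_one_spec_thirteen_thresholds(self, three_pop_cohort):
        gm, panel, _, sumstats, _ = three_pop_cohort
        specs = [pe.ClumpSpec(reference_population="ALL")]
        prs = pe.score_grid(gm, sumstats, gm, panel, specs)
        assert prs.scores.shape[1] == 13

    def test_figure_grid_layout_36_cells(self):
        pops = ("ALL", "P1", "P2", "P3", "P4", "P5")
        anc = sd.sample_ancestral_freqs(60, 41)
        pf = sd.balding_nichols_freqs(anc, (0.05,) * 5, 42)
        pf.index = ["P1", "P2", "P3", "P4", "P5"]
        gm, panel = sd.simulate_genotypes(pf, 30, block_size=3, within_block_r=0.4, seed=43)
        y, _ = sd.simulate_phenotype(gm, 10, 0.5, 44)
        ss = sd.run_gwas(gm, y)
        specs = pe.default_grid_specs(reference_populations=pops)
        prs = pe.score_grid(gm, ss, gm, panel, specs, thresholds=(5e-8, 1.0))
        assert prs.scores.shape[1] == 36  # 6 reference panels x 3 r^2 x 2 p_T

    def test_variant_counts_nondecreasing_in_p_t(self, three_pop_cohort):
        gm, panel, _, sumstats, _ = three_pop_cohort
        specs = [pe.ClumpSpec(reference_population="POP1", r2_threshold=0.2)]
        prs = pe.score_grid(gm, sumstats, gm, panel, specs)
        counts = prs.counts.iloc[0].to_numpy()
        assert (np.diff(counts) >= 0).all()

    def test_unknown_reference_population_raises(self, three_pop_cohort):
        gm, panel, _, sumstats, _ = three_pop_cohort
        with pytest.raises(KeyError):
            pe.score_grid(gm, sumstats, gm, panel, [pe.ClumpSpec(reference_population="XXX")])

    def test_orientation_invariance(self, three_pop_cohort):
        gm, panel, _, sumstats, _ = three_pop_cohort
        flipped = gm.subset_variants(np.arange(gm.n_variants))
        j = 7  # flip ref/alt labels and complement the dosage of one variant
        flipped.variants.loc[j, ["ref_allele", "alt_allele"]] = (
            gm.variants.loc[j, "alt_allele"], gm.variants.loc[j, "ref_allele"]
        )
        flipped.dosages[:, j] = 2.0 - flipped.dosages[:, j]
        specs = [pe.ClumpSpec(reference_population="ALL")]
        a = pe.score_grid(gm, sumstats, gm, panel, specs, thresholds=(0.05, 1.0))
        b = pe.score_grid(flipped, sumstats, gm, panel, specs, thresholds=(0.05, 1.0))
        # flipping w*d -> (-w)*(2-d) shifts every sample's score by the same
        # -2w, so invariance holds for centered scores (between-sample info)
        am = a.scores.to_numpy()
        bm = b.scores.to_numpy()
        np.testing.assert_allclose(am - am.mean(axis=0), bm - bm.mean(axis=0), atol=1e-9)
        assert (a.counts.to_numpy() == b.counts.to_numpy()).all()


def test_clump_spec_validation_and_label():
    with pytest.raises(ValueError):
        pe.ClumpSpec(r2_threshold=0.0)
    with pytest.raises(ValueError):
        pe.ClumpSpec(window_kb=0)
    assert pe.ClumpSpec(r2_threshold=0.05, reference_population="EUR").label == "EUR_r2_0.05"


def test_default_thresholds_are_valid():
    assert pe.validate_thresholds(pe.DEFAULT_THRESHOLDS) == pe.DEFAULT_THRESHOLDS
    with pytest.raises(ValueError):
        pe.validate_thresholds((0.5, 0.1))
    with pytest.raises(ValueError):
        pe.validate_thresholds(())
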