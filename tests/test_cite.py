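import numpy as np
import pandas as pd
import pytest

from mltiplet.cite import (
    AdtPositivityCaller,
    DEFAULT_EXCLUSIVE_PAIRS,
    DegenerateSeparationError,
    flag_cite_doublets,
    lda_threshold,
    probe_sensitivity,
    reference_populations,
)
from mltiplet.features import clr_adt
from mltiplet.simulate import spike_doublets


def brute_force_threshold(pos, neg, n_grid=2000):
    """Independent oracle: grid cut minimising balanced misclassification."""
    lo, hi = min(pos.min(), neg.min()), max(pos.max(), neg.max())
    grid = np.linspace(lo, hi, n_grid)
    # balanced error: miss rate on positives + false-positive rate on negatives
    err = [( (pos <= t).mean() + (neg > t).mean() ) / 2 for t in grid]
    return grid[int(np.argmin(err))]


class TestLdaThreshold:
    def test_midpoint_of_well_separated_gaussians(self):
        rng = np.random.default_rng(0)
        pos, neg = rng.normal(3, 1, 10_000), rng.normal(0, 1, 10_000)
        assert lda_threshold(pos, neg) == pytest.approx(1.5, abs=0.15)

    def test_matches_bruteforce_misclassification_cut(self):
        rng = np.random.default_rng(1)
        pos, neg = rng.normal(2.5, 0.8, 10_000), rng.normal(-0.5, 0.8, 10_000)
        t = lda_threshold(pos, neg)
        assert abs(t - brute_force_threshold(pos, neg)) < 0.05

    def test_identical_samples_degenerate(self):
        x = np.linspace(0, 1, 100)
        with pytest.raises(DegenerateSeparationError):
            lda_threshold(x, x)

    def test_translation_equivariance(self):
        rng = np.random.default_rng(2)
        pos, neg = rng.normal(3, 1, 500), rng.normal(0, 1, 500)
        t0 = lda_threshold(pos, neg)
        assert lda_threshold(pos + 2.5, neg + 2.5) == pytest.approx(t0 + 2.5, abs=1e-9)

    def test_unequal_priors_shift_matches_closed_form(self):
        rng = np.random.default_rng(3)
        pos, neg = rng.normal(3, 1, 50_000), rng.normal(0, 1, 50_000)
        t_eq = lda_threshold(pos, neg)
        t_sk = lda_threshold(pos, neg, priors=(0.2, 0.8))
        # shift = sigma^2 ln(pi_neg/pi_pos) / (mu_pos - mu_neg)
        expected = np.log(0.8 / 0.2) / 3.0
        assert t_sk - t_eq == pytest.approx(expected, rel=0.1)

    def test_too_few_values_errors(self):
        with pytest.raises(ValueError, match="at least"):
            lda_threshold([1.0] * 5, [0.0] * 50)


class TestReferenceAndSensitivity:
    LABELS = pd.Series(
        ["B cell"] * 3 + ["T cell"] * 4 + ["myeloid"] * 2,
        index=[f"b{i}" for i in range(9)],
    )

    def test_reference_lookup_returns_cluster_barcodes(self):
        refs = reference_populations(
            self.LABELS, {"CD3": {"pos": ["T cell"], "neg": ["B cell", "myeloid"]}}
        )
        pos, neg = refs["CD3"]
        assert set(pos) == {"b3", "b4", "b5", "b6"}
        assert set(neg) == {"b0", "b1", "b2", "b7", "b8"}

    def test_unknown_cell_type_errors(self):
        with pytest.raises(ValueError, match="absent"):
            reference_populations(self.LABELS, {"CD3": {"pos": ["NK"], "neg": ["B cell"]}})

    @pytest.mark.parametrize("n_called,expected,usable", [(80, 0.80, True), (70, 0.70, False), (0, 0.0, False)])
    def test_sensitivity_counting_and_strict_gate(self, n_called, expected, usable):
        barcodes = [f"c{i}" for i in range(100)]
        called = pd.Series([True] * n_called + [False] * (100 - n_called), index=barcodes)
        sens = probe_sensitivity(called, barcodes)
        assert sens == pytest.approx(expected)
        assert (sens > 0.70) is usable

    def test_empty_reference_is_nan(self):
        called = pd.Series([True], index=["c0"])
        assert np.isnan(probe_sensitivity(called, []))


def _manual_caller(thresholds: dict) -> AdtPositivityCaller:
    caller = AdtPositivityCaller()
    caller.thresholds_ = pd.Series(thresholds, dtype=float)
    caller.sensitivity_ = pd.Series(1.0, index=list(thresholds))
    caller.usable_ = pd.Series(True, index=list(thresholds))
    return caller


class TestFlagging:
    CLR = pd.DataFrame(
        {
            "CD19": [2.0, -1.0, 2.0, 2.0],
            "CD3": [2.0, 2.0, -1.0, 2.0],
            "CD4": [-1.0, 2.0, -1.0, 2.0],
        },
        index=["dbl", "t", "b", "triple"],
    )

    def _positivity(self):
        return _manual_caller({"CD19": 0.0, "CD3": 0.0, "CD4": 0.0}).transform(self.CLR)

    def test_exclusive_pair_fires(self):
        calls = flag_cite_doublets(self._positivity(), [("CD19", "CD3")])
        assert calls.loc["dbl", "flag"] and calls.loc["dbl", "pairs"] == "CD19+CD3"
        assert not calls.loc["b", "flag"] and not calls.loc["t", "flag"]

    def test_non_listed_copositivity_not_flagged(self):
        # CD3+CD4 co-positivity is expected on T cells and is not in the pair list
        calls = flag_cite_doublets(self._positivity(), [("CD19", "CD4")])
        assert not calls.loc["t", "flag"]
        assert ("CD3", "CD4") not in {tuple(sorted(p)) for p in DEFAULT_EXCLUSIVE_PAIRS}

    def test_all_triggering_pairs_recorded(self):
        calls = flag_cite_doublets(self._positivity(), [("CD19", "CD3"), ("CD19", "CD4")])
        assert set(calls.loc["triple", "pairs"].split(";")) == {"CD19+CD3", "CD19+CD4"}

    def test_pair_with_unusable_antibody_dropped(self):
        pos = self._positivity()
        usable = pd.Series({"CD19": True, "CD3": False, "CD4": True})
        with pytest.warns(UserWarning, match="dropped"):
            calls = flag_cite_doublets(pos, [("CD19", "CD3")], usable=usable)
        assert not calls["flag"].any()

    def test_self_pair_rejected(self):
        with pytest.raises(ValueError, match="self-pair"):
            flag_cite_doublets(self._positivity(), [("CD19", "CD19")])

    def test_lowering_threshold_only_adds_flags(self):
        rng = np.random.default_rng(4)
        clr = pd.DataFrame(
            rng.normal(0, 1, size=(300, 2)), columns=["CD19", "CD3"],
            index=[f"b{i}" for i in range(300)],
        )
        hi = _manual_caller({"CD19": 0.5, "CD3": 0.5}).transform(clr)
        lo = _manual_caller({"CD19": -0.5, "CD3": 0.5}).transform(clr)
        f_hi = flag_cite_doublets(hi, [("CD19", "CD3")])["flag"]
        f_lo = flag_cite_doublets(lo, [("CD19", "CD3")])["flag"]
        assert (f_lo | f_hi).equals(f_lo)  # hi-threshold flags are a subset


class TestPlantedDoubletRecovery:
    def test_mixed_lineage_doublets_recovered(self, small_dataset):
        spiked, truth = spike_doublets(small_dataset, 0.08, seed=21)
        labels = spiked.rna.obs["cell_type_truth"]
        singlet_labels = labels[~truth["is_doublet"]]
        clr = clr_adt(spiked.adt)
        ab_map = {
            "CD19": {"pos": ["B cell"], "neg": ["T cell", "myeloid"]},
            "CD3": {"pos": ["T cell"], "neg": ["B cell", "myeloid"]},
            "CD14": {"pos": ["myeloid"], "neg": ["B cell", "T cell"]},
            "CD16": {"pos": ["myeloid"], "neg": ["B cell", "T cell"]},
        }
        refs = reference_populations(singlet_labels, ab_map)
        caller = AdtPositivityCaller().fit(clr[list(ab_map)], refs)
        assert caller.usable_.all()
        calls = flag_cite_doublets(
            caller.transform(clr[list(ab_map)]),
            [("CD19", "CD3"), ("CD19", "CD14"), ("CD19", "CD16"), ("CD3", "CD14"), ("CD3", "CD16")],
            usable=caller.usable_,
        )
        mixed = truth.index[
            truth["is_doublet"] & (truth["subtype"] == "heterotypic")
        ]
        singlets = truth.index[~truth["is_doublet"]]
        assert calls.loc[mixed, "flag"].mean() >= 0.90
        assert calls.loc[singlets, "flag"].mean() <= 0.02
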