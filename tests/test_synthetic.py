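import numpy as np
import pandas as pd
import pytest

from radsig.firstorder import first_order_features
from radsig.mrmr import mrmr_select
from radsig.synthetic import (
    EFFECT_PRESETS,
    PhantomSpec,
    TableSpec,
    generate_feature_table,
    generate_phantom_cohort,
    generate_phantom_samples,
    split_assignment,
    split_cohort,
)
from radsig.texture import glrlm, glrlm_features, quantize

TINY = dict(volume_shape=(16, 16, 16), roi_semiaxes=(3.0, 5.0))


class TestSplit:
    def test_study_sized_split(self):
        groups = split_assignment(239, seed=0)
        assert (groups == "training").sum() == 160
        assert (groups == "validation").sum() == 79

    def test_three_samples(self):
        groups = split_assignment(3, seed=1)
        assert (groups == "training").sum() == 2
        assert (groups == "validation").sum() == 1

    def test_split_independent_of_label(self):
        # chi-square label x group p > 0.05 in >= 90% of 100 seeds
        from radsig.evaluation import chi2_from_counts

        rng = np.random.default_rng(0)
        n = 10000
        hits = 0
        for seed in range(100):
            labels = rng.integers(0, 2, n)
            groups = split_assignment(n, seed=seed)
            tr, va = labels[groups == "training"], labels[groups == "validation"]
            table = [[(tr == 0).sum(), (tr == 1).sum()],
                     [(va == 0).sum(), (va == 1).sum()]]
            _, p = chi2_from_counts(np.array(table))
            hits += p > 0.05
        assert hits >= 90

    def test_split_cohort_adds_group_column(self):
        manifest = pd.DataFrame({"sample_id": [f"s{i}" for i in range(30)]})
        out = split_cohort(manifest, seed=3)
        assert set(out["group"]) == {"training", "validation"}
        assert (out["group"] == "validation").sum() == 10


class TestPhantoms:
    def test_default_cohort_shape(self):
        spec = PhantomSpec()
        assert spec.n_train + spec.n_validation == 239
        assert spec.volume_shape == (48, 48, 48)

    def test_samples_structure_and_determinism(self):
        spec = PhantomSpec(n_train=4, n_validation=2, seed=11, **TINY)
        a = generate_phantom_samples(spec)
        b = generate_phantom_samples(spec)
        assert len(a) == 6
        for sa, sb in zip(a, b):
            assert sa.sample_id == sb.sample_id
            assert sa.label == sb.label and sa.group == sb.group
            np.testing.assert_array_equal(sa.volume.voxels, sb.volume.voxels)
            np.testing.assert_array_equal(sa.mask.voxels, sb.mask.voxels)
        assert {s.label for s in a} <= {"low", "high"}
        assert {s.group for s in a} == {"training", "validation"}

    def test_different_seed_different_data(self):
        a = generate_phantom_samples(PhantomSpec(n_train=3, n_validation=1, seed=1, **TINY))
        b = generate_phantom_samples(PhantomSpec(n_train=3, n_validation=1, seed=2, **TINY))
        assert not np.array_equal(a[0].volume.voxels, b[0].volume.voxels)

    def test_cohort_written_to_disk(self, tmp_path):
        spec = PhantomSpec(n_train=3, n_validation=1, seed=5, **TINY)
        manifest = generate_phantom_cohort(spec, tmp_path)
        assert len(manifest) == 4
        assert (tmp_path / "manifest.csv").exists()
        from radsig.preprocess import load_mask, load_volume

        v = load_volume(manifest.iloc[0]["image_path"])
        m = load_mask(manifest.iloc[0]["mask_path"])
        assert v.shape == (16, 16, 16) and m.voxels.sum() > 0

    def test_unknown_preset_rejected(self):
        with pytest.raises(ValueError, match="preset"):
            PhantomSpec(effect="extreme")

    def test_texture_contrast_monotone_over_presets(self):
        """Class separation of ROI texture features grows null->moderate->strong.

        The class signal is injected through the ROI texture (mean shift and
        spatial correlation length), so the standardized between-class gap of
        first-order Entropy and of run-length features must increase across
        the presets.  60 phantoms per preset keep the gap estimates stable.
        """

        def class_gaps(effect):
            spec = PhantomSpec(
                n_train=48, n_validation=12, seed=101, effect=effect,
                volume_shape=(24, 24, 24), roi_semiaxes=(4.0, 7.0),
            )
            vals = {"low": {"Entropy": [], "LRE": []},
                    "high": {"Entropy": [], "LRE": []}}
            for s in generate_phantom_samples(spec):
                fg = s.mask.voxels.astype(bool)
                fo = first_order_features(s.volume.voxels[fg], n_bins=32)
                levels, _ = quantize(s.volume.voxels, fg, 32)
                rf = glrlm_features(glrlm(levels, 32), int(fg.sum()))
                vals[s.label]["Entropy"].append(fo["Entropy"])
                vals[s.label]["LRE"].append(rf["Long Run Emphasis"])
            out = {}
            for f in ("Entropy", "LRE"):
                a, b = np.array(vals["high"][f]), np.array(vals["low"][f])
                out[f] = abs(a.mean() - b.mean()) / np.sqrt((a.var() + b.var()) / 2)
            return out

        gaps = [class_gaps(e) for e in ("null", "moderate", "strong")]
        for f in ("Entropy", "LRE"):
            series = [g[f] for g in gaps]
            assert series[0] < series[1] < series[2], (f, series)


class TestFeatureTables:
    def test_null_effect_no_signal(self):
        t, info = generate_feature_table(TableSpec(n=400, p=40, k_informative=5,
                                                   effect_size=0.0, seed=0))
        y = t.labels
        for j in range(t.p):
            a, b = t.values[y == 1, j], t.values[y == 0, j]
            d = (a.mean() - b.mean()) / np.sqrt((a.var() + b.var()) / 2)
            assert abs(d) < 3.0 / np.sqrt(min((y == 1).sum(), (y == 0).sum()))

    def test_planted_effect_size_recovered(self):
        t, info = generate_feature_table(TableSpec(n=2000, p=30, k_informative=4,
                                                   effect_size=1.5, seed=1))
        y = t.labels
        for j in np.flatnonzero(info):
            a, b = t.values[y == 1, j], t.values[y == 0, j]
            d = (a.mean() - b.mean()) / np.sqrt((a.var() + b.var()) / 2)
            assert abs(d - 1.5) < 0.1

    def test_study_shaped_table(self):
        t, info = generate_feature_table(TableSpec(seed=2))
        assert t.values.shape == (239, 431)
        assert info.sum() == 9
        assert (t.groups == "training").sum() == 160

    def test_block_correlation_in_nuisance(self):
        t, info = generate_feature_table(TableSpec(n=3000, p=20, k_informative=0,
                                                   rho=0.5, block_size=10, seed=3))
        c = np.corrcoef(t.values[:, 0], t.values[:, 1])[0, 1]
        far = np.corrcoef(t.values[:, 0], t.values[:, 15])[0, 1]
        assert abs(c - 0.5) < 0.1
        assert abs(far) < 0.1

    def test_mrmr_recovers_planted_features(self):
        """k=9 selection recalls >= 2/3 of planted columns at default effects."""
        t, info = generate_feature_table(TableSpec(seed=4))
        train = t.subset_rows(t.groups == "training")
        res = mrmr_select(train, k=9)
        truth = {t.feature_names[j] for j in np.flatnonzero(info)}
        recall = len(truth & set(res.selected)) / len(truth)
        assert recall >= 2.0 / 3.0

    def test_determinism(self):
        a, _ = generate_feature_table(TableSpec(n=50, p=10, seed=9))
        b, _ = generate_feature_table(TableSpec(n=50, p=10, seed=9))
        np.testing.assert_array_equal(a.values, b.values)
        np.testing.assert_array_equal(a.labels, b.labels)
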