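"""Reference selection, drift regression and internal-standard scaling."""

import numpy as np
import pandas as pd
import pytest

from vitreomics.calibration import (
    CalibrationError,
    apply_alignment,
    fit_alignment,
    normalize_intensities,
    select_internal_standards,
    select_reference_features,
)

from conftest import jittered_feature_tables


def _tables_with_presence(masses, times, presence, rng):
    """presence[i] = list of sample indices in which truth feature i occurs."""
    n_samples = max(s for ss in presence for s in ss) + 1
    tables = {f"s{i:02d}": [] for i in range(n_samples)}
    for i, samples in enumerate(presence):
        for s in samples:
            tables[f"s{s:02d}"].append(
                (
                    masses[i] * (1 + rng.normal(0, 2e-6)),
                    times[i] + rng.normal(0, 0.02),
                    1e4,
                )
            )
    return {
        k: pd.DataFrame(v, columns=["neutral_mass", "migration_time_min", "intensity"])
        for k, v in tables.items()
    }


class TestReferenceSelection:
    def test_frequency_threshold_boundary(self):
        rng = np.random.default_rng(0)
        masses = np.array([1000.0, 2000.0, 3000.0])
        times = np.array([25.0, 40.0, 45.0])
        # with 10 samples: feature 0 at 40%, feature 1 at 30%, feature 2 at 100%
        presence = [list(range(4)), [4, 5, 6], list(range(10))]
        tables = _tables_with_presence(masses, times, presence, rng)
        refmap = select_reference_features(tables, threshold=0.35)
        got = sorted(refmap.references["canonical_mass"].round(0))
        assert got == [1000.0, 3000.0]  # the 30% feature is excluded

    def test_no_reference_is_an_error(self):
        rng = np.random.default_rng(1)
        masses = np.arange(1000.0, 1010.0)
        times = np.linspace(20, 45, 10)
        presence = [[i % 10] for i in range(10)]  # every feature a singleton
        tables = _tables_with_presence(masses, times, presence, rng)
        with pytest.raises(CalibrationError):
            select_reference_features(tables, threshold=0.35)

    def test_too_few_samples_rejected(self):
        df = pd.DataFrame(columns=["neutral_mass", "migration_time_min", "intensity"])
        with pytest.raises(CalibrationError):
            select_reference_features({"a": df, "b": df})

    def test_invariant_peptides_recovered_at_high_detection(self):
        rng = np.random.default_rng(2)
        masses = np.sort(rng.uniform(850, 3900, 30))
        times = rng.uniform(20, 49, 30)
        presence = [
            [s for s in range(10) if rng.random() < 0.9] for _ in range(30)
        ]
        tables = _tables_with_presence(masses, times, presence, rng)
        refmap = select_reference_features(tables, threshold=0.35)
        assert len(refmap.references) >= 27


def _refmap_and_sample(drift=(1.0, 0.0), jitter=0.0, n=30, seed=3):
    rng = np.random.default_rng(seed)
    masses = np.sort(rng.uniform(850, 3900, n))
    times = np.sort(rng.uniform(20, 49, n))
    refs = pd.DataFrame({"canonical_mass": masses, "canonical_time": times})
    slope, intercept = drift
    observed = pd.DataFrame(
        {
            "neutral_mass": masses,
            "migration_time_min": slope * times + intercept + rng.normal(0, jitter, n),
            "intensity": np.full(n, 1e4),
        }
    )
    from vitreomics.calibration import ReferenceMap

    return ReferenceMap(references=refs), observed


class TestAlignment:
    def test_identity_fit(self):
        refmap, observed = _refmap_and_sample()
        model = fit_alignment(observed, refmap, sample_id="s")
        assert model.time_slope == pytest.approx(1.0, abs=1e-9)
        assert model.time_intercept == pytest.approx(0.0, abs=1e-9)
        assert model.mass_slope == pytest.approx(1.0, abs=1e-9)

    def test_drift_recovery(self):
        refmap, observed = _refmap_and_sample(drift=(1.05, 0.3), jitter=0.02)
        model = fit_alignment(observed, refmap, sample_id="s")
        slope, intercept = model.drift_estimate
        assert slope == pytest.approx(1.05, abs=0.005)
        assert intercept == pytest.approx(0.3, abs=0.05)

    def test_too_few_matches_is_flagged_failure(self):
        refmap, observed = _refmap_and_sample(n=4)
        with pytest.raises(CalibrationError, match="4 matched"):
            fit_alignment(observed, refmap, sample_id="s")

    def test_gross_slope_is_calibration_failure(self):
        refmap, observed = _refmap_and_sample(drift=(3.0, 0.0))
        with pytest.raises(CalibrationError):
            fit_alignment(observed, refmap, sample_id="s", trim_outliers=False)

    def test_apply_roundtrip_and_intensity_preservation(self):
        refmap, observed = _refmap_and_sample(drift=(1.05, 0.3))
        model = fit_alignment(observed, refmap, sample_id="s")
        aligned = apply_alignment(observed, model)
        assert len(aligned) == len(observed)
        assert np.allclose(aligned["intensity"], observed["intensity"])
        # forward-drifting the aligned times reproduces the observations
        fslope, fint = model.drift_estimate
        back = fslope * aligned["migration_time_min"] + fint
        assert np.allclose(back, observed["migration_time_min"], atol=1e-9)

    def test_alignment_shrinks_reference_scatter(self):
        rng = np.random.default_rng(7)
        masses = np.sort(rng.uniform(850, 3900, 25))
        times = np.sort(rng.uniform(20, 49, 25))
        from vitreomics.calibration import ReferenceMap

        refmap = ReferenceMap(
            references=pd.DataFrame({"canonical_mass": masses, "canonical_time": times})
        )
        raw, aligned = [], []
        for s in range(8):
            slope = 1 + rng.normal(0, 0.02)
            inter = rng.normal(0, 0.3)
            obs = pd.DataFrame(
                {
                    "neutral_mass": masses * (1 + rng.normal(0, 2e-6, 25)),
                    "migration_time_min": slope * times + inter + rng.normal(0, 0.02, 25),
                    "intensity": np.full(25, 1e4),
                }
            )
            model = fit_alignment(obs, refmap, sample_id=f"s{s}")
            raw.append(obs["migration_time_min"].to_numpy())
            aligned.append(apply_alignment(obs, model)["migration_time_min"].to_numpy())
        sd_raw = np.vstack(raw).std(axis=0).mean()
        sd_aligned = np.vstack(aligned).std(axis=0).mean()
        assert sd_aligned < sd_raw


def _matrix(values, sample_ids):
    df = pd.DataFrame(values, columns=sample_ids)
    df.index = [f"cp{i}" for i in range(len(df))]
    df.insert(0, "frequency", df[sample_ids].notna().mean(axis=1))
    df.insert(0, "time", 30.0)
    df.insert(0, "mass", 1000.0)
    return df


class TestNormalization:
    def test_doubled_sample_restored(self):
        sids = ["a", "b", "c"]
        mat = _matrix([[10.0, 10.0, 20.0], [30.0, 30.0, 60.0], [50.0, 50.0, 100.0]], sids)
        labels = {"a": "case", "b": "case", "c": "control"}
        out, scaler = normalize_intensities(mat, ["cp0", "cp1", "cp2"], labels)
        assert scaler.factors["c"] == pytest.approx(0.5)
        assert np.allclose(out[sids].loc["cp1"], 30.0)

    def test_identical_samples_give_unit_factors(self):
        sids = ["a", "b", "c"]
        mat = _matrix([[10.0] * 3, [20.0] * 3], sids)
        _, scaler = normalize_intensities(mat, ["cp0", "cp1"], {s: "case" for s in sids})
        assert all(f == pytest.approx(1.0) for f in scaler.factors.values())

    def test_idempotence(self):
        rng = np.random.default_rng(11)
        sids = [f"s{i}" for i in range(6)]
        vals = rng.lognormal(3, 0.4, (5, 6))
        mat = _matrix(vals, sids)
        std = [f"cp{i}" for i in range(5)]
        labels = {s: "case" for s in sids}
        out, _ = normalize_intensities(mat, std, labels)
        _, scaler2 = normalize_intensities(out, std, labels)
        assert all(f == pytest.approx(1.0, abs=1e-9) for f in scaler2.factors.values())

    def test_sample_with_few_standards_flagged_not_scaled(self):
        sids = ["a", "b", "c"]
        vals = [[10.0, 10.0, np.nan], [20.0, 20.0, np.nan], [30.0, 30.0, 60.0]]
        mat = _matrix(vals, sids)
        out, scaler = normalize_intensities(
            mat, ["cp0", "cp1", "cp2"], {s: "case" for s in sids}, min_detected=3
        )
        assert scaler.factors["c"] == 1.0
        assert "c" in scaler.flagged_samples
        assert out.loc["cp2", "c"] == 60.0

    def test_gain_removal_reduces_standard_cv(self):
        """Lognormal(0, 0.3) per-sample gains: scaling shrinks the CV."""
        rng = np.random.default_rng(13)
        wins = 0
        for _ in range(50):
            sids = [f"s{i}" for i in range(12)]
            gains = rng.lognormal(0, 0.3, 12)
            base = rng.lognormal(4, 0.5, 8)
            vals = np.outer(base, gains) * rng.lognormal(0, 0.05, (8, 12))
            mat = _matrix(vals, sids)
            std = [f"cp{i}" for i in range(8)]
            out, _ = normalize_intensities(mat, std, {s: "case" for s in sids})
            cv = lambda block: (block.std(axis=1) / block.mean(axis=1)).mean()
            if cv(out[sids].loc[std]) < cv(mat[sids].loc[std]):
                wins += 1
        assert wins >= 48

    def test_empty_standards_rejected(self):
        mat = _matrix([[1.0, 1.0]], ["a", "b"])
        with pytest.raises(ValueError):
            normalize_intensities(mat, [], {"a": "case", "b": "case"})


class TestStandardSelection:
    def test_frequency_and_null_association_gate(self):
        rng = np.random.default_rng(17)
        sids = [f"c{i}" for i in range(10)] + [f"k{i}" for i in range(10)]
        labels = {s: ("case" if s.startswith("c") else "control") for s in sids}
        null_row = np.full(20, 100.0)
        assoc_row = np.concatenate([rng.lognormal(5, 0.2, 10), rng.lognormal(3, 0.2, 10)])
        rare_row = np.where(rng.random(20) < 0.5, np.nan, 100.0)
        mat = _matrix(np.vstack([null_row, assoc_row, rare_row]), sids)
        chosen = select_internal_standards(mat, labels, k=5)
        assert "cp0" in chosen  # frequent and unassociated
        assert "cp1" not in chosen  # disease-associated
        assert "cp2" not in chosen  # too rare
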