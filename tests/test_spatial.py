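import numpy as np
import pytest

from preictal.exceptions import ConfigurationError, DegenerateSignalError
from preictal.io import Recording
from preictal.pipeline import PipelineConfig
from preictal.experiment import extract_class_segments
from preictal.spatial import (
    CSPFilter,
    apply_csp,
    average_reference,
    fit_csp,
    normalized_covariance,
)


def _rec(samples, fs=256.0):
    samples = np.asarray(samples, dtype=float)
    return Recording(samples=samples, fs=fs,
                     channel_names=[f"c{i}" for i in range(samples.shape[0])])


def _toy_classes(rng, n_segments=20, n_ch=2, n_t=500):
    """Class 1 concentrates variance on channel 0, class 2 on channel 1."""
    c1, c2 = [], []
    for _ in range(n_segments):
        seg = rng.standard_normal((n_ch, n_t))
        seg[0] *= 5.0
        c1.append(seg)
        seg = rng.standard_normal((n_ch, n_t))
        seg[1] *= 5.0
        c2.append(seg)
    return c1, c2


class TestAverageReference:
    def test_constant_channels(self):
        rec = _rec([np.ones(100), 3 * np.ones(100)])
        np.testing.assert_allclose(average_reference(rec).samples, 2.0)

    def test_antisymmetric_channels_cancel(self, rng):
        x = rng.standard_normal(200)
        np.testing.assert_allclose(average_reference(_rec([x, -x])).samples, 0.0,
                                   atol=1e-12)

    def test_matches_per_sample_mean_oracle(self, rng):
        samples = rng.standard_normal((4, 1000))
        out = average_reference(_rec(samples)).samples
        oracle = np.array([np.mean(samples[:, t]) for t in range(1000)])
        np.testing.assert_allclose(out, oracle, rtol=1e-12)

    def test_single_channel_rejected(self, rng):
        with pytest.raises(ConfigurationError):
            average_reference(_rec(rng.standard_normal((1, 100))))


class TestNormalizedCovariance:
    def test_unit_trace(self, rng):
        C = normalized_covariance(rng.standard_normal((5, 300)))
        assert np.isclose(np.trace(C), 1.0)
        np.testing.assert_allclose(C, C.T)

    def test_orthogonal_rows_give_identity(self):
        t = np.arange(512) / 512
        X = np.vstack([np.sin(2 * np.pi * 8 * t), np.cos(2 * np.pi * 8 * t)])
        C = normalized_covariance(X)
        np.testing.assert_allclose(C, np.eye(2) / 2, atol=1e-3)

    def test_matches_brute_force(self, rng):
        X = rng.standard_normal((3, 500))
        raw = X @ X.T
        np.testing.assert_allclose(
            normalized_covariance(X), raw / np.trace(raw), rtol=1e-12
        )

    def test_zero_segment_rejected(self):
        with pytest.raises(DegenerateSignalError):
            normalized_covariance(np.zeros((3, 100)))


class TestFitCSP:
    def test_planted_variance_puts_weight_on_class1_channel(self, rng):
        c1, c2 = _toy_classes(rng)
        filt = fit_csp(c1, c2)
        assert np.argmax(np.abs(filt.projection)) == 0

    def test_identical_classes_give_half_eigenvalues(self, rng):
        segs = [rng.standard_normal((3, 400)) for _ in range(10)]
        filt = fit_csp(segs, segs)
        np.testing.assert_allclose(filt.D, 0.5, atol=1e-10)

    def test_whitening_identities(self, rng):
        c1, c2 = _toy_classes(rng, n_ch=4)
        filt = fit_csp(c1, c2)
        n = filt.n_channels
        assert np.max(np.abs(filt.w @ filt.R @ filt.w.T - np.eye(n))) < 1e-8
        assert np.max(np.abs(filt.S1 + filt.S2 - np.eye(n))) < 1e-8

    def test_eigenvalue_complementarity(self, rng):
        c1, c2 = _toy_classes(rng, n_ch=5)
        filt = fit_csp(c1, c2)
        lam2 = np.sort(np.linalg.eigvalsh(filt.S2))[::-1]
        np.testing.assert_allclose(np.sort(filt.D + lam2[::-1]), 1.0, atol=1e-8)

    def test_empty_class_rejected(self, rng):
        with pytest.raises(ConfigurationError):
            fit_csp([], [rng.standard_normal((2, 100))])

    def test_matches_mne_csp_variance_ratio(self, rng):
        """Independent cross-check: the class-variance ratio achieved by our
        top CSP component agrees with mne's CSP implementation."""
        mne = pytest.importorskip("mne")
        c1, c2 = _toy_classes(rng, n_segments=30, n_ch=3)
        filt = fit_csp(c1, c2)

        epochs = np.array(c1 + c2)
        labels = np.array([1] * len(c1) + [2] * len(c2))
        csp = mne.decoding.CSP(n_components=3, transform_into="csp_space",
                               norm_trace=True)
        csp.fit(epochs, labels)

        def ratio(w):
            v1 = np.mean([np.var(w @ s) for s in c1])
            v2 = np.mean([np.var(w @ s) for s in c2])
            return max(v1 / v2, v2 / v1)

        ours = ratio(filt.projection)
        theirs = max(ratio(f) for f in csp.filters_)
        assert ours == pytest.approx(theirs, rel=0.1)


class TestApplyCSP:
    def _filter_with_projection(self, rng, proj):
        c1, c2 = _toy_classes(rng, n_ch=len(proj))
        filt = fit_csp(c1, c2)
        filt.projection = np.asarray(proj, dtype=float)
        return filt

    def test_unit_projection_selects_channel(self, rng):
        samples = rng.standard_normal((3, 200))
        filt = self._filter_with_projection(rng, [0.0, 1.0, 0.0])
        out = apply_csp(filt, _rec(samples))
        np.testing.assert_allclose(out.samples, samples[1])

    def test_linearity(self, rng):
        samples = rng.standard_normal((2, 150))
        c1, c2 = _toy_classes(rng)
        filt = fit_csp(c1, c2)
        once = apply_csp(filt, _rec(samples)).samples
        twice = apply_csp(filt, _rec(2 * samples)).samples
        np.testing.assert_allclose(twice, 2 * once, rtol=1e-12)

    def test_matches_dot_product_oracle(self, rng):
        samples = rng.standard_normal((2, 100))
        c1, c2 = _toy_classes(rng)
        filt = fit_csp(c1, c2)
        out = apply_csp(filt, _rec(samples)).samples
        oracle = np.array([filt.projection @ samples[:, t] for t in range(100)])
        np.testing.assert_allclose(out, oracle, rtol=1e-12)

    def test_dimension_mismatch_rejected(self, rng):
        c1, c2 = _toy_classes(rng, n_ch=3)
        filt = fit_csp(c1, c2)
        with pytest.raises(ConfigurationError):
            apply_csp(filt, _rec(rng.standard_normal((5, 100))))


class TestSerialization:
    def test_json_round_trip(self, rng, tmp_path):
        c1, c2 = _toy_classes(rng, n_ch=3)
        filt = fit_csp(c1, c2)
        back = CSPFilter.from_json(filt.to_json(tmp_path / "csp.json"))
        np.testing.assert_array_equal(back.projection, filt.projection)
        np.testing.assert_array_equal(back.filter_matrix, filt.filter_matrix)


def test_csp_discriminates_at_least_as_well_as_averaging(seizure_session):
    """On a labeled synthetic session the CSP surrogate's preictal/interictal
    variance ratio should not fall below the averaging surrogate's."""
    rec, ann = seizure_session
    config = PipelineConfig(preictal_horizon_min=10.0)
    pre, inter = extract_class_segments(rec, ann, config)
    filt = fit_csp(pre, inter)

    def ratio(surrogate):
        fs = rec.fs
        (p0, p1), = ann.intervals_for("preictal")
        (i0, i1), = ann.intervals_for("interictal")
        x = surrogate.samples
        return (np.var(x[int(p0 * fs) : int(p1 * fs)])
                / np.var(x[int(i0 * fs) : int(i1 * fs)]))

    assert ratio(apply_csp(filt, rec)) >= ratio(average_reference(rec))
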