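import math

import numpy as np
import pytest

from gaitseg.feature_extraction import (
    FEATURE_CHANNELS,
    FeatureRanking,
    extract_features,
    feature_names,
    magnitude,
    rank_features_svm,
    select_top,
)
from gaitseg.signal_model import IMURecording, Segment


def _segment(data, fs=100.0, label=None):
    n = len(data["ax"])
    rec = IMURecording(time=np.arange(n) / fs, fs=fs, **data)
    return Segment(rec, 0, n, activity_label=label)


def _random_segment(rng, n=100):
    return _segment({c: rng.normal(size=n) for c in
                     ("ax", "ay", "az", "gx", "gy", "gz")})


# ----- independent definitional oracles -------------------------------------

def brute_mean(x):
    return sum(x) / len(x)


def brute_median(x):
    s = sorted(x)
    n = len(s)
    return s[n // 2] if n % 2 else (s[n // 2 - 1] + s[n // 2]) / 2


def brute_sd(x):
    m = brute_mean(x)
    return math.sqrt(sum((v - m) ** 2 for v in x) / (len(x) - 1))


def brute_moment_ratio(x, p):
    m = brute_mean(x)
    m2 = sum((v - m) ** 2 for v in x) / len(x)
    mp = sum((v - m) ** p for v in x) / len(x)
    return mp / m2 ** (p / 2)


def brute_quantile(x, q):
    s = sorted(x)
    h = (len(s) - 1) * q
    lo = math.floor(h)
    return s[lo] + (h - lo) * (s[min(lo + 1, len(s) - 1)] - s[lo])


def brute_corr(x, y):
    mx, my = brute_mean(x), brute_mean(y)
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = math.sqrt(sum((a - mx) ** 2 for a in x) * sum((b - my) ** 2 for b in y))
    return num / den


def brute_dft_mag(x, k):
    n = len(x)
    re = sum(v * math.cos(-2 * math.pi * k * j / n) for j, v in enumerate(x))
    im = sum(v * math.sin(-2 * math.pi * k * j / n) for j, v in enumerate(x))
    return math.hypot(re, im)


class TestMagnitude:
    def test_3_4_5(self):
        np.testing.assert_allclose(magnitude([3.0], [4.0], [0.0]), [5.0])

    def test_zero(self):
        np.testing.assert_allclose(magnitude([0.0], [0.0], [0.0]), [0.0])

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            magnitude([1, 2], [1], [1, 2])

    def test_rotation_invariance(self, rng):
        # fixed rotation (30 deg about z then 40 deg about x)
        a, b = np.radians(30), np.radians(40)
        Rz = np.array([[np.cos(a), -np.sin(a), 0],
                       [np.sin(a), np.cos(a), 0], [0, 0, 1]])
        Rx = np.array([[1, 0, 0], [0, np.cos(b), -np.sin(b)],
                       [0, np.sin(b), np.cos(b)]])
        V = rng.normal(size=(3, 50))
        W = Rx @ Rz @ V
        np.testing.assert_allclose(
            magnitude(*W), magnitude(*V), rtol=0, atol=1e-9
        )


class TestExtractFeatures:
    def test_exactly_152_named_features(self, rng):
        fv = extract_features(_random_segment(rng))
        assert len(fv.values) == 152
        assert len(set(fv.names)) == 152
        assert list(fv.names) == feature_names()

    def test_family_counts(self):
        names = feature_names()
        assert sum(n.startswith("corr_") for n in names) == 56
        assert sum(n.split("_")[0] in
                   ("mean", "median", "skewness", "kurtosis", "sd", "iqr")
                   for n in names) == 48
        assert sum(n.split("_")[0] in
                   ("energy", "fft1", "fft2", "fft3", "fft4", "fft5")
                   for n in names) == 48

    def test_too_short_segment_names_minimum(self, rng):
        seg = _random_segment(rng, n=7)
        with pytest.raises(ValueError, match="8"):
            extract_features(seg)

    def test_constant_channel_degenerate_values(self, rng):
        data = {c: rng.normal(size=64) for c in ("ay", "az", "gx", "gy", "gz")}
        data["ax"] = np.full(64, 2.5)
        fv = extract_features(_segment(data))
        assert fv["mean_ax"] == pytest.approx(2.5)
        assert fv["median_ax"] == pytest.approx(2.5)
        assert fv["sd_ax"] == 0.0
        assert fv["iqr_ax"] == pytest.approx(0.0, abs=1e-12)
        assert fv["skewness_ax"] == 0.0
        assert fv["kurtosis_ax"] == 0.0
        for k in range(1, 6):
            assert fv[f"fft{k}_ax"] == pytest.approx(0.0, abs=1e-9)
        # correlation against a zero-variance channel is defined as 0
        assert fv["corr_ax_ay"] == 0.0

    def test_perfect_linear_dependence_corr_one(self, rng):
        data = {c: rng.normal(size=64) for c in ("ax", "az", "gx", "gy", "gz")}
        data["ay"] = 2.0 * data["ax"] + 1.0
        fv = extract_features(_segment(data))
        assert fv["corr_ax_ay"] == pytest.approx(1.0, abs=1e-9)

    def test_energy_equals_mean_square_parseval(self):
        n = 100
        t = np.arange(n)
        data = {c: np.zeros(n) for c in ("ay", "az", "gx", "gy", "gz")}
        data["ax"] = np.sin(2 * np.pi * 2 * t / n)  # 2 cycles per segment
        data["ay"] = np.ones(n)  # keep other magnitudes sane
        fv = extract_features(_segment(data))
        assert fv["energy_ax"] == pytest.approx(np.mean(data["ax"] ** 2), abs=1e-6)

    def test_correlation_symmetry(self, rng):
        fv = extract_features(_random_segment(rng))
        for a in FEATURE_CHANNELS:
            for b in FEATURE_CHANNELS:
                if a < b:
                    assert abs(fv[f"corr_{a}_{b}"] - fv[f"corr_{b}_{a}"]) < 1e-12

    def test_pure_function_of_samples(self, rng):
        data = {c: rng.normal(size=80) for c in
                ("ax", "ay", "az", "gx", "gy", "gz")}
        seg1 = _segment(data)
        # same samples embedded mid-recording
        pad = {c: np.concatenate([rng.normal(size=30), data[c],
                                  rng.normal(size=20)]) for c in data}
        rec2 = IMURecording(time=np.arange(130) / 100.0, fs=100.0, **pad)
        seg2 = Segment(rec2, 30, 110)
        np.testing.assert_array_equal(
            extract_features(seg1).values, extract_features(seg2).values
        )

    def test_statistics_match_definitional_oracles(self):
        rng = np.random.default_rng(77)
        seg = _random_segment(rng, n=53)
        fv = extract_features(seg)
        chans = {c: seg.channel(c) for c in ("ax", "ay", "az", "gx", "gy", "gz")}
        chans["amag"] = np.sqrt(chans["ax"]**2 + chans["ay"]**2 + chans["az"]**2)
        chans["gmag"] = np.sqrt(chans["gx"]**2 + chans["gy"]**2 + chans["gz"]**2)
        for ch, x in chans.items():
            x = list(map(float, x))
            assert fv[f"mean_{ch}"] == pytest.approx(brute_mean(x), abs=1e-9)
            assert fv[f"median_{ch}"] == pytest.approx(brute_median(x), abs=1e-9)
            assert fv[f"sd_{ch}"] == pytest.approx(brute_sd(x), abs=1e-9)
            assert fv[f"skewness_{ch}"] == pytest.approx(
                brute_moment_ratio(x, 3), abs=1e-9
            )
            assert fv[f"kurtosis_{ch}"] == pytest.approx(
                brute_moment_ratio(x, 4), abs=1e-9
            )
            assert fv[f"iqr_{ch}"] == pytest.approx(
                brute_quantile(x, 0.75) - brute_quantile(x, 0.25), abs=1e-9
            )
            assert fv[f"energy_{ch}"] == pytest.approx(
                sum(v * v for v in x) / len(x), abs=1e-9
            )
            for k in range(1, 6):
                assert fv[f"fft{k}_{ch}"] == pytest.approx(
                    brute_dft_mag(x, k), abs=1e-7
                )
        assert fv["corr_gz_gx"] == pytest.approx(
            brute_corr(list(chans["gz"]), list(chans["gx"])), abs=1e-9
        )


class TestRankFeatures:
    def _toy(self, rng, n_per=20, n_feat=6, informative=2):
        X = rng.normal(size=(2 * n_per, n_feat))
        y = np.array(["A"] * n_per + ["B"] * n_per)
        X[:n_per, informative] += 4.0
        return X, y

    def test_separating_feature_ranked_first(self, rng):
        X, y = self._toy(rng)
        ranking = rank_features_svm(X, y, names=[f"f{j}" for j in range(6)])
        assert ranking.names[0] == "f2"

    def test_duplicated_column_equal_importance_adjacent_ranks(self, rng):
        X, y = self._toy(rng)
        X = np.column_stack([X, X[:, 2]])
        names = [f"f{j}" for j in range(6)] + ["f2_copy"]
        ranking = rank_features_svm(X, y, names=names)
        i, j = ranking.names.index("f2"), ranking.names.index("f2_copy")
        assert abs(i - j) == 1
        assert ranking.scores[i] == pytest.approx(ranking.scores[j], abs=1e-6)

    def test_constant_feature_zero_importance(self, rng):
        X, y = self._toy(rng)
        X[:, 5] = 3.14
        ranking = rank_features_svm(X, y, names=[f"f{j}" for j in range(6)])
        assert ranking.scores[ranking.names.index("f5")] == 0.0

    def test_single_class_rejected(self, rng):
        X = rng.normal(size=(10, 4))
        with pytest.raises(ValueError, match="two classes"):
            rank_features_svm(X, ["A"] * 10)

    def test_scores_non_increasing(self, rng):
        X, y = self._toy(rng)
        ranking = rank_features_svm(X, y)
        assert all(a >= b for a, b in zip(ranking.scores, ranking.scores[1:]))


class TestSelectTop:
    @pytest.fixture
    def ranking(self):
        names = tuple(f"f{j}" for j in range(152))
        scores = tuple(float(152 - j) for j in range(152))
        return FeatureRanking(names=names, scores=scores)

    def test_all(self, ranking):
        assert select_top(ranking, 152) == list(ranking.names)

    def test_default_twenty(self, ranking):
        assert len(select_top(ranking, 20)) == 20
        assert select_top(ranking, 20) == list(ranking.names[:20])

    @pytest.mark.parametrize("k", [0, -1, 153])
    def test_out_of_range(self, ranking, k):
        with pytest.raises(ValueError):
            select_top(ranking, k)
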