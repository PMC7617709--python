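import numpy as np
import pandas as pd
import pytest

from tmseegkit.microstates import (LabelSequence, backfit,
                                   canonical_templates, gmfp_peaks,
                                   grand_mean_templates, modified_kmeans,
                                   ms_parameters, ms_rm_anova,
                                   sort_templates, spatial_correlation,
                                   MicrostateModel)
from tmseegkit.synth_data import RestingConfig, synth_resting
from tmseegkit.tanova import map_gfp


def _orthonormal_maps(rng, k, n_ch):
    m = rng.standard_normal((k, n_ch))
    m -= m.mean(axis=1, keepdims=True)
    q, _ = np.linalg.qr(m.T)
    maps = q[:, :k].T
    return maps / map_gfp(maps)[:, None]


class TestGmfpPeaks:
    def test_sinusoid_peaks_twice_per_cycle(self, rng):
        srate, dur, f = 500.0, 4.0, 7.0
        t = np.arange(int(srate * dur)) / srate
        topo = rng.standard_normal(8)
        topo -= topo.mean()
        data = np.outer(topo, np.sin(2 * np.pi * f * t))
        peaks = gmfp_peaks(data, srate)
        # GFP = |sin|: two maxima per cycle (both polarities)
        assert peaks.shape[0] == pytest.approx(2 * f * dur, abs=2)

    def test_monotone_gfp_no_peaks(self):
        t = np.linspace(0.0, 1.0, 1000)
        data = np.vstack([t, -t])  # GFP strictly increasing
        with pytest.raises(ValueError, match="no GFP peaks"):
            gmfp_peaks(data, 400.0)

    def test_needs_two_seconds(self, rng):
        with pytest.raises(ValueError, match="2 s"):
            gmfp_peaks(rng.standard_normal((4, 100)), 500.0)

    def test_peak_count_on_markov_data(self):
        cfg = RestingConfig(duration_s=20.0, srate=250.0, snr=8.0, seed=5)
        data, labels, _ = synth_resting(cfg)
        peaks = gmfp_peaks(data, cfg.srate)
        # envelope oscillates at the carrier rate: one peak per cycle
        expected = cfg.carrier_hz * cfg.duration_s
        assert abs(peaks.shape[0] - expected) / expected < 0.35


class TestModifiedKmeans:
    def test_single_topography_k1(self, rng):
        topo = _orthonormal_maps(rng, 1, 12)[0]
        signs = rng.choice([1.0, -1.0], 40)
        maps = np.outer(signs, topo)
        model = modified_kmeans(maps, k=1, restarts=2, seed=0)
        assert abs(spatial_correlation(model.templates[0], topo)) > 0.9999
        assert model.gev == pytest.approx(1.0, abs=1e-9)

    def test_two_orthogonal_topographies(self, rng):
        topos = _orthonormal_maps(rng, 2, 16)
        which = rng.integers(2, size=80)
        amps = rng.uniform(0.5, 2.0, 80) * rng.choice([1.0, -1.0], 80)
        maps = topos[which] * amps[:, None]
        maps += 0.02 * rng.standard_normal(maps.shape)
        model = modified_kmeans(maps, k=2, restarts=5, seed=1)
        c = np.abs(spatial_correlation(model.templates[:, None, :],
                                       topos[None, :, :]))
        # each true topography recovered by one template
        assert c.max(axis=0).min() > 0.99

    def test_gev_non_decreasing_in_k(self, rng):
        cfg = RestingConfig(duration_s=10.0, srate=250.0, snr=2.0, seed=9)
        data, _, _ = synth_resting(cfg)
        peaks = gmfp_peaks(data, cfg.srate)
        gevs = [modified_kmeans(peaks, k=k, restarts=4, seed=0).gev
                for k in range(2, 7)]
        assert all(b >= a - 1e-6 for a, b in zip(gevs, gevs[1:]))

    def test_needs_enough_maps(self, rng):
        with pytest.raises(ValueError, match="at least"):
            modified_kmeans(rng.standard_normal((30, 8)), k=4)


class TestGrandMeanTemplates:
    def test_identical_models_unchanged(self, rng):
        topos = _orthonormal_maps(rng, 4, 20)
        model = MicrostateModel(topos, ("C1", "C2", "C3", "C4"))
        grand = grand_mean_templates([model] * 5)
        c = np.abs(spatial_correlation(grand.templates, topos))
        assert np.all(c > 1 - 1e-9)
        assert grand.shared_variance == pytest.approx(1.0, abs=1e-9)

    def test_sign_flips_do_not_matter(self, rng):
        topos = _orthonormal_maps(rng, 4, 20)
        a = MicrostateModel(topos, ("C1", "C2", "C3", "C4"))
        b = MicrostateModel(-topos, ("C1", "C2", "C3", "C4"))
        grand = grand_mean_templates([a, b, a, b])
        c = np.abs(spatial_correlation(grand.templates, topos))
        assert np.all(c > 1 - 1e-9)

    def test_shared_variance_in_unit_interval(self, rng):
        models = []
        base = _orthonormal_maps(rng, 4, 20)
        for _ in range(6):
            noisy = base + 0.3 * rng.standard_normal(base.shape)
            models.append(MicrostateModel(noisy, ("C1", "C2", "C3", "C4")))
        grand = grand_mean_templates(models)
        assert 0.0 <= grand.shared_variance <= 1.0

    def test_k_mismatch_rejected(self, rng):
        a = MicrostateModel(_orthonormal_maps(rng, 4, 20),
                            ("C1", "C2", "C3", "C4"))
        b = MicrostateModel(_orthonormal_maps(rng, 3, 20), ("C1", "C2", "C3"))
        with pytest.raises(ValueError, match="share k"):
            grand_mean_templates([a, b])


class TestSortTemplates:
    def test_self_sort_identity(self, montage):
        canon = canonical_templates(montage)
        out = sort_templates(canon, canon)
        assert out.labels == ("A", "B", "C", "D")
        c = spatial_correlation(out.templates, canon.templates)
        assert np.allclose(c, 1.0, atol=1e-9)

    def test_shuffled_copy_recovered(self, montage, rng):
        canon = canonical_templates(montage)
        perm = rng.permutation(4)
        signs = rng.choice([1.0, -1.0], 4)
        shuffled = MicrostateModel(signs[:, None] * canon.templates[perm],
                                   ("C1", "C2", "C3", "C4"))
        out = sort_templates(shuffled, canon)
        c = spatial_correlation(out.templates, canon.templates)
        assert np.allclose(np.abs(c), 1.0, atol=1e-9)
        assert np.all(c > 0)  # signs aligned to reference

    def test_committed_canonical_fixture_matches(self, montage):
        from pathlib import Path

        csv = (Path(__file__).parents[1] / "src" / "tmseegkit" / "data"
               / "canonical_templates.csv")
        df = pd.read_csv(csv)
        canon = canonical_templates(montage)
        assert list(df.channel) == list(montage.names)
        assert np.allclose(df[["A", "B", "C", "D"]].to_numpy().T,
                           canon.templates, atol=1e-9)

    def test_canonical_layout(self, montage):
        canon = canonical_templates(montage)
        t = {lbl: canon.templates[i] for i, lbl in enumerate(canon.labels)}
        i = montage.index
        # A: left-posterior vs right-anterior diagonal; B mirrored
        assert (t["A"][i("P7")] - t["A"][i("F8")]) * \
               (t["B"][i("P8")] - t["B"][i("F7")]) > 0
        # C: occipito-frontal gradient
        assert abs(t["C"][i("Oz")] - t["C"][i("Fpz")]) > 0.5
        # D: fronto-central focal
        assert t["D"][i("FCz")] == pytest.approx(t["D"].max(), abs=1e-9)

    def test_k_mismatch_rejected(self, montage, rng):
        canon = canonical_templates(montage)
        other = MicrostateModel(rng.standard_normal((3, montage.n_channels)),
                                ("C1", "C2", "C3"))
        with pytest.raises(ValueError, match="k mismatch"):
            sort_templates(other, canon)


class TestBackfit:
    def test_template_times_envelope(self, montage, rng):
        canon = canonical_templates(montage)
        env = np.abs(np.sin(np.linspace(0.1, 9.0, 500))) + 0.1
        data = np.outer(canon.templates[2], env)
        seq = backfit(data, canon, 250.0)
        assert np.all(seq.labels == 2)

    def test_polarity_invariance(self, montage):
        canon = canonical_templates(montage)
        env = np.linspace(0.5, 1.5, 300)
        up = backfit(np.outer(canon.templates[1], env), canon, 250.0)
        down = backfit(np.outer(-canon.templates[1], env), canon, 250.0)
        assert np.array_equal(up.labels, down.labels)

    def test_markov_accuracy_over_90pct(self):
        cfg = RestingConfig(duration_s=30.0, srate=250.0, snr=4.0, seed=21)
        data, labels, mont = synth_resting(cfg)
        canon = canonical_templates(mont)
        seq = backfit(data, canon, cfg.srate)
        assert np.mean(seq.labels == labels) > 0.9

    def test_global_sign_flip_invariance(self):
        cfg = RestingConfig(duration_s=10.0, srate=250.0, snr=3.0, seed=2)
        data, _, mont = synth_resting(cfg)
        canon = canonical_templates(mont)
        a = backfit(data, canon, cfg.srate)
        b = backfit(-data, canon, cfg.srate)
        assert np.array_equal(a.labels, b.labels)


class TestMsParameters:
    def test_constant_label(self):
        seq = LabelSequence(np.zeros(1000, dtype=int), 500.0, ("A", "B"))
        p = ms_parameters(seq)
        assert p.value("A", "coverage") == pytest.approx(100.0)
        assert p.value("A", "occurrence") == pytest.approx(0.5)  # 1 per 2 s
        assert p.value("A", "duration") == pytest.approx(2000.0)
        assert p.value("B", "coverage") == 0.0

    def test_strict_alternation(self):
        # A(50 ms)/B(50 ms) over 1 s at 1 kHz
        block = np.r_[np.zeros(50, int), np.ones(50, int)]
        seq = LabelSequence(np.tile(block, 10), 1000.0, ("A", "B"))
        p = ms_parameters(seq)
        for cls in ("A", "B"):
            assert p.value(cls, "occurrence") == pytest.approx(10.0)
            assert p.value(cls, "duration") == pytest.approx(50.0)
            assert p.value(cls, "coverage") == pytest.approx(50.0)

    def test_coverage_sums_to_100(self, rng):
        seq = LabelSequence(rng.integers(0, 4, 5000), 250.0,
                            ("A", "B", "C", "D"))
        p = ms_parameters(seq)
        assert p.table.coverage.sum() == pytest.approx(100.0)

    def test_occurrence_duration_consistency(self, rng):
        seq = LabelSequence(rng.integers(0, 4, 5000), 250.0,
                            ("A", "B", "C", "D"))
        p = ms_parameters(seq)
        total = (p.table.occurrence * p.table.duration).sum() / 1000.0
        assert total == pytest.approx(1.0, rel=1e-9)

    def test_markov_dwell_recovered(self):
        cfg = RestingConfig(duration_s=60.0, srate=250.0, snr=5.0, seed=33)
        data, _, mont = synth_resting(cfg)
        seq = backfit(data, canonical_templates(mont), cfg.srate)
        p = ms_parameters(seq)
        mean_dur = float(p.table.duration.mean())
        assert abs(mean_dur - 65.0) / 65.0 < 0.10


def _null_params(rng, n_subjects=8):
    params = {}
    for s in range(n_subjects):
        for c in ("active", "sham"):
            for t in ("pre", "post"):
                labels = _markov_seq(rng, 2500, 4, 16.0)
                seq = LabelSequence(labels, 250.0, ("A", "B", "C", "D"))
                params[(f"S{s}", c, t)] = ms_parameters(seq)
    return params


def _markov_seq(rng, n, k, dwell):
    out = np.empty(n, dtype=int)
    state, i = int(rng.integers(k)), 0
    while i < n:
        run = min(int(rng.geometric(1.0 / dwell)), n - i)
        out[i:i + run] = state
        nxt = int(rng.integers(k - 1))
        state = nxt if nxt < state else nxt + 1
        i += run
    return out


class TestMsRmAnova:
    def test_null_table_shape_and_rates(self, rng):
        table = ms_rm_anova(_null_params(rng))
        assert len(table) == 4 * 3 * 3  # classes x parameters x effects
        assert (table.p > 0.001).all()

    def test_injected_duration_effect_detected(self):
        mods = {("active", "post"): (2.0, 1.0, 1.0, 1.0),
                ("sham", "post"): (2.0, 1.0, 1.0, 1.0)}
        cfg = RestingConfig(n_subjects=6, duration_s=20.0, srate=250.0,
                            snr=4.0, dwell_modifiers=mods, seed=4)
        params = {}
        for s in range(cfg.n_subjects):
            for c in ("active", "sham"):
                for t in ("pre", "post"):
                    data, _, mont = synth_resting(cfg, (c, t), s)
                    seq = backfit(data, canonical_templates(mont), cfg.srate)
                    params[(f"S{s}", c, t)] = ms_parameters(seq)
        table = ms_rm_anova(params)
        row = table[(table["class"] == "A") & (table.parameter == "duration")
                    & (table.effect == "time")]
        assert float(row.p.iloc[0]) < 0.05
        assert float(row.delta_active.iloc[0]) > 0

    def test_delta_sign_convention(self, rng):
        params = _null_params(rng, 6)
        table = ms_rm_anova(params)
        subjects = sorted({k[0] for k in params})
        manual = np.mean([
            params[(s, "active", "post")].value("B", "coverage")
            - params[(s, "active", "pre")].value("B", "coverage")
            for s in subjects])
        row = table[(table["class"] == "B") & (table.parameter == "coverage")]
        assert float(row.delta_active.iloc[0]) == pytest.approx(manual)
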