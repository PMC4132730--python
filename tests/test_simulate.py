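"""Tests of the two-pathway crossover simulator."""

import numpy as np
import pytest
from scipy import stats as sps

from tetrakit import (
    ConfigurationError,
    CrossoverEvent,
    SimulationConfig,
    generate_tetrad,
    map_distance,
    place_crossovers,
    resolve_chromatids,
    simulate_meiocytes,
    simulate_tetrad_population,
    tally,
)
from tetrakit.simulate import CLASS_I, draw_event_batch, _trace_batch


def events_from_flat(rows, pos, cm, cp, n):
    """Group flat event arrays into per-meiosis CrossoverEvent lists."""
    off = np.concatenate([[0], np.cumsum(np.bincount(rows, minlength=n))])
    return [
        [
            CrossoverEvent(float(pos[k]), CLASS_I, (int(cm[k]), int(cp[k])))
            for k in range(off[m], off[m + 1])
        ]
        for m in range(n)
    ]


class TestEventPlacement:
    def test_zero_intensity_always_empty(self):
        cfg = SimulationConfig(lambda1=0.0, lambda2=0.0)
        rng = np.random.default_rng(0)
        for _ in range(20):
            assert place_crossovers(cfg, rng) == []

    def test_invalid_intensities_rejected(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(lambda1=-1.0)
        with pytest.raises(ConfigurationError):
            SimulationConfig(lambda2=float("nan"))
        with pytest.raises(ConfigurationError):
            SimulationConfig(nu=0.0)
        with pytest.raises(ConfigurationError):
            SimulationConfig(lambda1=0.0, lambda2=0.0, obligate_co=True)

    def test_poisson_mean_count_and_exponential_spacing(self):
        """nu = 1 placement is a Poisson process: mean count lambda1 and
        exponential inter-event distances (probability-integral transform
        accounts for window censoring of the last gap)."""
        cfg = SimulationConfig(nu=1.0, lambda1=2.0, lambda2=0.0)
        rng = np.random.default_rng(11)
        n = 10_000
        rows, pos, _ = draw_event_batch(cfg, rng, n)
        counts = np.bincount(rows, minlength=n)
        se = counts.std(ddof=1) / np.sqrt(n)
        assert abs(counts.mean() - 2.0) < 3 * se

        rate = cfg.lambda1 / cfg.chrom_length
        u = []
        off = np.concatenate([[0], np.cumsum(counts)])
        for m in range(n):
            p = pos[off[m]:off[m + 1]]
            for prev, nxt in zip(p[:-1], p[1:]):
                gap = nxt - prev
                bound = cfg.chrom_length - prev
                # exponential gap conditioned on fitting in the window
                u.append(-np.expm1(-rate * gap) / -np.expm1(-rate * bound))
        assert len(u) > 3000
        assert sps.kstest(u, "uniform").pvalue > 0.01

    def test_gamma_shape_reduces_spacing_cv(self):
        """Spacing CV falls with the gamma shape (CV = 1/sqrt(nu))."""
        cvs = {}
        for nu in (1.0, 10.0):
            cfg = SimulationConfig(nu=nu, lambda1=2.0, lambda2=0.0)
            rng = np.random.default_rng(12)
            rows, pos, _ = draw_event_batch(cfg, rng, 10_000)
            counts = np.bincount(rows, minlength=10_000)
            gaps = []
            off = np.concatenate([[0], np.cumsum(counts)])
            for m in range(10_000):
                p = pos[off[m]:off[m + 1]]
                gaps.extend(np.diff(p))
            gaps = np.asarray(gaps)
            cvs[nu] = gaps.std() / gaps.mean()
        assert cvs[10.0] < cvs[1.0]

    def test_stationarity_uniform_positions(self):
        """With nu = 1 event positions are uniform over the chromosome."""
        cfg = SimulationConfig(nu=1.0, lambda1=2.0, lambda2=0.0)
        rng = np.random.default_rng(13)
        _, pos, _ = draw_event_batch(cfg, rng, 10_000)
        assert pos.size >= 10_000
        p = sps.kstest(pos, "uniform", args=(0, cfg.chrom_length)).pvalue
        assert p > 0.01

    def test_obligate_rejection_matches_conditional_distribution(self):
        """Rejection sampling equals conditioning on >= 1 event: positions
        (KS) and count distributions (chi-square) agree."""
        base = SimulationConfig(nu=1.0, lambda1=0.6, lambda2=0.0)
        rng = np.random.default_rng(14)
        rows_o, pos_o, _ = draw_event_batch(base.replace(obligate_co=True), rng, 20_000)
        counts_o = np.bincount(rows_o, minlength=20_000)
        assert (counts_o >= 1).all()

        rows_f, pos_f, _ = draw_event_batch(base, rng, 60_000)
        counts_f = np.bincount(rows_f, minlength=60_000)
        keep = counts_f >= 1
        pos_keep = pos_f  # every event row has >= 1 event by construction
        assert sps.ks_2samp(pos_o, pos_keep).pvalue > 0.01

        kmax = 5
        o = np.bincount(np.minimum(counts_o, kmax), minlength=kmax + 1)[1:]
        f = np.bincount(np.minimum(counts_f[keep], kmax), minlength=kmax + 1)[1:]
        table = np.vstack([o, f])
        table = table[:, table.sum(axis=0) > 0]
        assert sps.chi2_contingency(table).pvalue > 0.01


class TestChromatidResolution:
    def test_empty_list(self):
        assert resolve_chromatids([], np.random.default_rng(0)) == []

    def test_single_event_uniform_over_four_pairs(self):
        rng = np.random.default_rng(21)
        picks = [
            resolve_chromatids([CrossoverEvent(0.1, CLASS_I)], rng)[0].chromatids
            for _ in range(10_000)
        ]
        freq = np.zeros(4)
        for m, p in picks:
            freq[2 * m + p] += 1
        freq /= 10_000
        se = np.sqrt(0.25 * 0.75 / 10_000)
        assert np.all(np.abs(freq - 0.25) < 3 * se)

    def test_two_events_independent(self):
        rng = np.random.default_rng(22)
        evs = [CrossoverEvent(0.1, CLASS_I), CrossoverEvent(0.2, CLASS_I)]
        table = np.zeros((4, 4))
        for _ in range(10_000):
            r = resolve_chromatids(evs, rng)
            a = 2 * r[0].chromatids[0] + r[0].chromatids[1]
            b = 2 * r[1].chromatids[0] + r[1].chromatids[1]
            table[a, b] += 1
        assert sps.chi2_contingency(table).pvalue > 0.01


class TestTetradGeneration:
    def test_no_events_gives_parental_ditype(self):
        cfg = SimulationConfig()
        t = generate_tetrad(cfg, [])
        counts = {tuple(s) for s in t.spores}
        assert counts == {(1, 1, 1), (0, 0, 0)}
        assert (t.spores.sum(axis=0) == 2).all()

    def test_single_crossover_between_markers_1_and_2(self):
        """One exchange in I2a on chromatids (m1, p1): tetratype in I2a,
        parental ditype in I2b (hand-traced chromatid diagram)."""
        cfg = SimulationConfig()
        ev = CrossoverEvent(0.17, CLASS_I, (0, 0))
        t = generate_tetrad(cfg, [ev])
        spores = {tuple(s) for s in t.spores}
        assert spores == {(1, 0, 0), (1, 1, 1), (0, 1, 1), (0, 0, 0)}

    def test_unsorted_events_rejected(self):
        cfg = SimulationConfig()
        evs = [
            CrossoverEvent(0.3, CLASS_I, (0, 0)),
            CrossoverEvent(0.1, CLASS_I, (0, 0)),
        ]
        with pytest.raises(RuntimeError):
            generate_tetrad(cfg, evs)

    def test_mendelian_segregation_always(self):
        """Every generated tetrad segregates 2:2 at every locus."""
        cfg = SimulationConfig(nu=2.0, lambda1=3.0, lambda2=1.0, n_meioses=5000, seed=31)
        pop = simulate_tetrad_population(cfg)
        assert (pop.genotypes.sum(axis=1) == 2).all()

    def test_scalar_and_vectorised_tracing_agree(self):
        """The batched tracer reproduces per-meiosis tracing exactly."""
        cfg = SimulationConfig(nu=1.0, lambda1=3.0, lambda2=1.0)
        rng = np.random.default_rng(32)
        n = 500
        rows, pos, _ = draw_event_batch(cfg, rng, n)
        cm = rng.integers(0, 2, rows.size).astype(np.int8)
        cp = rng.integers(0, 2, rows.size).astype(np.int8)
        G = _trace_batch(n, rows, pos, cm, cp, cfg.marker_positions, "coupling")
        for m, evs in enumerate(events_from_flat(rows, pos, cm, cp, n)):
            t = generate_tetrad(cfg, evs, m)
            np.testing.assert_array_equal(t.spores, G[m])


class TestPopulation:
    def test_determinism_under_seed(self):
        cfg = SimulationConfig(nu=3.0, lambda1=1.5, lambda2=0.3, n_meioses=2000, seed=7)
        a = simulate_tetrad_population(cfg)
        b = simulate_tetrad_population(cfg)
        assert a.genotypes.tobytes() == b.genotypes.tobytes()

    def test_small_interval_distance_recovery(self, null_population, null_config):
        """Perkins estimate of a 5 cM interval under Poisson placement is
        within 3 SE of its nominal length (mapping-function-free limit)."""
        counts = tally(null_population)
        for interval, length in zip(("I2a", "I2b"), null_config.interval_lengths):
            d = map_distance(counts, interval)
            assert abs(d.cM - 100 * length) < 3 * d.sd

    def test_class_ii_intensity_increases_distance(self):
        """Doubling lambda2 strictly increases the Perkins distance."""
        base = SimulationConfig(
            nu=8.0, lambda1=0.8, lambda2=0.4, n_meioses=50_000, seed=33
        )
        d1 = map_distance(tally(simulate_tetrad_population(base)), "I2a")
        d2 = map_distance(
            tally(simulate_tetrad_population(base.replace(lambda2=0.8, seed=34))),
            "I2a",
        )
        assert d2.cM > d1.cM

    def test_coefficient_of_coincidence(self, null_counts, interference_counts):
        """CoC across the adjacent intervals is 1 under Poisson placement
        and below 1 under strong gamma interference."""

        def coc_with_se(counts, n_boot=200, seed=0):
            rec = counts.counts[1:, :].sum() + counts.counts[0, 1:].sum()
            p11 = counts.counts[1:, 1:].sum() / counts.n
            pa = counts.counts[1:, :].sum() / counts.n
            pb = counts.counts[:, 1:].sum() / counts.n
            coc = p11 / (pa * pb)
            rng = np.random.default_rng(seed)
            flat = counts.counts.ravel()
            reps = rng.multinomial(counts.n, flat / counts.n, size=n_boot)
            reps = reps.reshape(n_boot, 3, 3)
            p11b = reps[:, 1:, 1:].sum(axis=(1, 2)) / counts.n
            pab = reps[:, 1:, :].sum(axis=(1, 2)) / counts.n
            pbb = reps[:, :, 1:].sum(axis=(1, 2)) / counts.n
            return coc, np.std(p11b / (pab * pbb), ddof=1)

        coc0, se0 = coc_with_se(null_counts)
        assert abs(coc0 - 1.0) < 3 * se0
        coc1, _ = coc_with_se(interference_counts)
        assert coc1 < 0.5


class TestMeiocytes:
    def test_obligate_crossover_five_bivalents(self):
        cfg = SimulationConfig(
            nu=8.0, lambda1=0.8, lambda2=0.08, obligate_co=True,
            n_chrom_pairs=5, n_meioses=1000, seed=41,
        )
        for m in simulate_meiocytes(cfg):
            assert m.bivalents == 5
            assert m.univalent_pairs == 0

    def test_zero_intensity_all_univalents(self):
        cfg = SimulationConfig(lambda1=0.0, lambda2=0.0, n_meioses=200, seed=42)
        assert all(m.bivalents == 0 for m in simulate_meiocytes(cfg))

    @pytest.mark.parametrize("lam1,lam2", [(0.8, 0.0), (0.5, 0.5)])
    def test_poisson_void_probability(self, lam1, lam2):
        """Mean bivalents matches 5 * (1 - exp(-lambda)) for Poisson totals."""
        cfg = SimulationConfig(
            nu=1.0, lambda1=lam1, lambda2=lam2, n_meioses=20_000, seed=43
        )
        biv = np.array([m.bivalents for m in simulate_meiocytes(cfg)])
        lam = lam1 + lam2
        expected = 5 * (1 - np.exp(-lam))
        se = biv.std(ddof=1) / np.sqrt(biv.size)
        assert abs(biv.mean() - expected) < 3 * se
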