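"""Forward BGS simulator: DFE draws, site classes, engine correctness."""

import numpy as np
import pandas as pd
import pytest

from linkedsel.bgs import (
    DFEComponent,
    DFESpec,
    SimulationConfig,
    assign_site_classes,
    default_dfe,
    draw_s,
    relative_timeseries,
    run_forward,
    run_neutral_control,
)
from linkedsel.demography import ConstantModel, default_model


class TestDFE:
    def test_default_mixture_weights_and_means(self):
        dfe = default_dfe()
        w = {c.label: c.weight for c in dfe.components}
        assert w["conserved_noncoding"] == pytest.approx(0.6606)
        assert w["coding"] == pytest.approx(0.3394)
        means = {c.label: c.mean_s for c in dfe.components}
        # scaled-mean arithmetic: alpha_scaled / beta
        assert means["conserved_noncoding"] == pytest.approx(0.00515625 / 0.0415)
        assert means["coding"] == pytest.approx(0.00040244 / 0.184)

    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError):
            DFESpec([DFEComponent(0.5, 1.0, 1.0, 1.0)])

    def test_draw_means_match_gamma_moments(self, rng):
        dfe = default_dfe()
        coding = DFESpec([DFEComponent(1.0, 6.25, 0.184, 6.25 / 0.00040244)])
        s = draw_s(coding, rng, 200_000)
        assert (s < 0).all()
        assert (-s).mean() == pytest.approx(0.00040244 / 0.184, rel=0.02)
        cnc = DFESpec([DFEComponent(1.0, 80.11, 0.0415, 80.11 / 0.00515625)])
        s2 = draw_s(cnc, rng, 200_000)
        assert (-s2).mean() == pytest.approx(0.12425, rel=0.02)

    def test_zero_weight_component_never_drawn(self, rng):
        dfe = DFESpec([
            DFEComponent(1.0, 100.0, 1.0, 1.0),       # |s| ~ 100 -> clamped to 1
            DFEComponent(0.0, 1e-9, 1e9, 1.0),
        ])
        s = draw_s(dfe, rng, 10_000)
        assert np.allclose(s, -1.0)

    def test_clamped_at_lethal(self, rng):
        dfe = DFESpec([DFEComponent(1.0, 1e4, 1.0, 1.0)])
        assert (draw_s(dfe, rng, 100) >= -1.0).all()

    def test_shape_convention_preserves_mean(self, rng):
        a, b, tnr = 6.25, 0.184, 6.25 / 0.00040244
        mom = DFESpec([DFEComponent(1.0, a, b, tnr)], convention="moments")
        shp = DFESpec([DFEComponent(1.0, a, b, tnr)], convention="shape")
        s1 = -draw_s(mom, rng, 300_000)
        s2 = -draw_s(shp, rng, 300_000)
        assert s1.mean() == pytest.approx(s2.mean(), rel=0.05)
        # shape 0.184 is far more dispersed than shape 6.25
        assert s2.std() > 2 * s1.std()


class TestSiteClasses:
    def test_f_del_zero_all_neutral(self):
        cfg = SimulationConfig(f_del=0.0, flank_bp=10_000)
        scm = assign_site_classes(cfg, seed=0)
        assert scm.del_count == 0

    def test_f_del_one_single_component(self):
        dfe = DFESpec([
            DFEComponent(1.0, 80.11, 0.0415, 80.11 / 0.00515625),
            DFEComponent(0.0, 6.25, 0.184, 6.25 / 0.00040244),
        ])
        cfg = SimulationConfig(f_del=1.0, flank_bp=5_000, dfe=dfe)
        scm = assign_site_classes(cfg, seed=0)
        assert scm.del_count == cfg.selected_bp
        assert scm.component_counts(2).tolist() == [cfg.selected_bp, 0]

    def test_binomial_moments_at_default_fraction(self):
        cfg = SimulationConfig(f_del=0.2046, flank_bp=100_000)
        scm = assign_site_classes(cfg, seed=1)
        n = cfg.selected_bp
        expect = 0.2046 * n
        sd = np.sqrt(n * 0.2046 * (1 - 0.2046))
        assert abs(scm.del_count - expect) < 5 * sd
        counts = scm.component_counts(2)
        assert counts.sum() == scm.del_count
        assert counts[0] / scm.del_count == pytest.approx(0.6606, abs=0.02)

    def test_deleterious_u_arithmetic(self):
        cfg = SimulationConfig()
        assert cfg.deleterious_u == pytest.approx(1.66e-8 * 0.2046 * 2_000_000)


def tiny_three_pop_config(**kw):
    kw.setdefault("rescale_q", 200.0)
    kw.setdefault("sample_size", 10)
    kw.setdefault("burn_in_factor", 1.0)
    kw.setdefault("output_interval", 2000.0)
    kw.setdefault("flank_bp", 50_000)
    kw.setdefault("core_bp", 30_000)
    kw.setdefault("seed", 2)
    return SimulationConfig(**kw)


class TestEngine:
    def test_three_population_mechanics(self):
        """Splits occur, all lineages are sampled, time axis is consistent."""
        cfg = tiny_three_pop_config()
        res = run_forward(cfg, replicates=2)
        df = res.df
        assert set(df["pop"]) == {"AFR", "B", "EUR", "EASN"}
        m = default_model()
        for pop, t_oldest in [("B", m.t_ooa_split), ("EUR", m.t_eur_easn_split)]:
            sub = df[df["pop"] == pop]
            assert sub["t_gens_ago"].max() <= t_oldest + cfg.rescale_q
        final = df[df["t_gens_ago"] == 0.0]
        assert set(final["pop"]) == {"AFR", "EUR", "EASN"}
        assert (df["pi"] >= 0).all() and (df["psi"] >= 0).all()

    def test_seed_reproducible(self):
        cfg = tiny_three_pop_config(seed=7)
        a = run_forward(cfg, replicates=2).df
        b = run_forward(cfg, replicates=2).df
        pd.testing.assert_frame_equal(a, b)

    def test_sample_size_error_names_population(self):
        cfg = tiny_three_pop_config(sample_size=5000)
        with pytest.raises(ValueError, match="AFR"):
            run_forward(cfg, replicates=1)

    def test_control_is_core_only_null(self):
        cfg = tiny_three_pop_config()
        ctrl = run_neutral_control(cfg, replicates=2)
        assert (ctrl.df["pi"] >= 0).all()
        # identical sampling schedule as the BGS arm
        bgs = run_forward(cfg, replicates=2)
        assert sorted(ctrl.df["t_gens_ago"].unique()) == sorted(
            bgs.df["t_gens_ago"].unique()
        )

    def test_relative_timeseries_identity(self):
        cfg = tiny_three_pop_config()
        res = run_forward(cfg, replicates=2)
        rel = relative_timeseries(res, res)
        assert np.allclose(rel["pi_ratio"].dropna(), 1.0)

    def test_constant_model_requires_duration(self):
        with pytest.raises(ValueError, match="run_generations"):
            run_forward(
                SimulationConfig(demography=ConstantModel(50), flank_bp=0,
                                 f_del=0.0, sample_size=10),
                replicates=1,
            )


class TestNeutralExpectations:
    def test_equilibrium_pi_matches_coalescent(self):
        """Neutral engine: E[pi] = 4 N mu within 3 SE over replicates."""
        n = 150
        cfg = SimulationConfig(
            flank_bp=0, core_bp=30_000, f_del=0.0,
            demography=ConstantModel(n), run_generations=300.0,
            burn_in_factor=10.0, sample_size=40, output_interval=150.0, seed=5,
        )
        res = run_forward(cfg, replicates=40)
        fin = res.df[res.df["t_gens_ago"] == 0.0]
        expect = 4 * n * cfg.mu
        se = fin["pi"].std(ddof=1) / np.sqrt(len(fin))
        assert abs(fin["pi"].mean() - expect) < 3 * se

    def test_sfs_close_to_neutral_shape(self):
        """Aggregated unfolded SFS roughly follows xi_i proportional to 1/i."""
        n = 100
        cfg = SimulationConfig(
            flank_bp=0, core_bp=50_000, f_del=0.0, mu=5e-8,
            demography=ConstantModel(n), run_generations=100.0,
            burn_in_factor=10.0, sample_size=12, output_interval=100.0, seed=6,
        )
        res = run_forward(cfg, replicates=30)
        # recompute class counts from singleton fraction: psi * L / (pi-based S)
        fin = res.df[res.df["t_gens_ago"] == 0.0]
        sing = fin["psi"].mean() * cfg.core_bp
        seg = fin["segsites"].mean()
        a = np.sum(1.0 / np.arange(1, 12))
        assert sing / seg == pytest.approx(1 / a, rel=0.25)

    def test_rescaling_invariance_neutral(self):
        """Rescaled runs agree on theta-scale diversity within Monte Carlo error."""
        means = {}
        ses = {}
        for q in (2.0, 4.0):
            cfg = SimulationConfig(
                flank_bp=0, core_bp=30_000, f_del=0.0,
                demography=ConstantModel(240), run_generations=200.0,
                burn_in_factor=8.0, sample_size=30, output_interval=100.0,
                rescale_q=q, seed=8,
            )
            res = run_forward(cfg, replicates=30)
            fin = res.df[res.df["t_gens_ago"] == 0.0]
            means[q] = fin["pi"].mean()
            ses[q] = fin["pi"].std(ddof=1) / np.sqrt(len(fin))
        diff = abs(means[2.0] - means[4.0])
        assert diff < 3 * np.hypot(ses[2.0], ses[4.0])
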