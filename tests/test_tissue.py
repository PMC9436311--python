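"""Lattice geometry, growth-factor field, cell events and lineage tracking."""

import dataclasses
import math

import numpy as np
import pytest

from epidermis_evo import (SimConfig, Simulation, place_daughter, solve_gf,
                           track_lineages)


def run_days(sim, days, **kw):
    return sim.run(days, **kw)


# ---------------------------------------------------------------------------
# geometry and initialization
# ---------------------------------------------------------------------------

class TestInit:
    def test_one_mm2_gives_66_voxel_side(self):
        cfg = SimConfig(biopsy_area_mm2=1.0, cell_size_um=15.0)
        assert cfg.lx == cfg.ly == 66
        sim = Simulation(cfg)
        assert sim.state.n_basal == 66 * 66
        assert sim.state.n_cells == 66 * 66  # basal layer only at t = 0
        assert sim.state.clock == 0.0

    def test_area_within_one_voxel_row(self):
        cfg = SimConfig(biopsy_area_mm2=0.25)
        row_area = cfg.lx * (cfg.cell_size_um * 1e-3) ** 2
        assert abs(cfg.area_mm2 - 0.25) <= row_area

    def test_initial_cells_are_founders(self, tiny_config):
        sim = Simulation(tiny_config)
        assert np.all(sim.state.geno[:, :, 0] == 0)
        assert np.all(sim.state.geno[:, :, 1:] == -1)

    def test_same_seed_same_initial_state(self, tiny_config):
        a, b = Simulation(tiny_config), Simulation(tiny_config)
        assert np.array_equal(a.state.geno, b.state.geno)
        assert np.allclose(a.state.gf, b.state.gf)

    def test_gf_decreases_away_from_source_after_init(self, tiny_config):
        sim = Simulation(tiny_config)
        profile = sim.state.gf.mean(axis=(0, 1))
        assert profile[0] == pytest.approx(tiny_config.gf_source)
        assert np.all(np.diff(profile) <= 1e-12)

    def test_nonpositive_dims_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(biopsy_area_mm2=-1.0)
        with pytest.raises(ValueError):
            SimConfig(lz=0)


# ---------------------------------------------------------------------------
# growth-factor field
# ---------------------------------------------------------------------------

class TestGrowthFactor:
    def test_empty_lattice_no_decay_uniform(self):
        cfg = SimConfig(biopsy_area_mm2=0.0144, lz=12, gf_decay=0.0,
                        gf_consumption=0.0, gf_tol=1e-9)
        sim = Simulation(cfg)
        sim.state.geno[:] = -1  # remove every cell: Laplace, one Dirichlet face
        solve_gf(sim.state, cfg)
        assert np.allclose(sim.state.gf, cfg.gf_source, atol=1e-6)

    def test_decay_profile_matches_cosh_closed_form(self):
        """No cells, weak decay: the z-profile solves D u'' = lambda u with
        u(0)=s0 and a no-flux top, i.e. u = s0 cosh(k (L - z)) / cosh(k L)."""
        cfg = SimConfig(biopsy_area_mm2=0.0144, lz=40, gf_decay=0.01,
                        gf_consumption=0.0, gf_diffusion=1.0, gf_tol=1e-9)
        sim = Simulation(cfg)
        sim.state.geno[:] = -1
        sim.state.gf[:] = 0.0
        solve_gf(sim.state, cfg)
        z = np.arange(cfg.lz)
        k = math.sqrt(cfg.gf_decay / cfg.gf_diffusion)
        L = cfg.lz - 0.5  # no-flux plane sits half a voxel past the top center
        expected = cfg.gf_source * np.cosh(k * (L - z)) / math.cosh(k * L)
        profile = sim.state.gf.mean(axis=(0, 1))
        assert np.max(np.abs(profile - expected) / expected) < 0.01

    def test_doubling_consumption_lowers_gf(self, tiny_config):
        sim = Simulation(tiny_config)
        sim.run(30, sample_every=None)
        base = sim.state.gf.mean()
        cfg2 = dataclasses.replace(tiny_config, gf_consumption=2 * tiny_config.gf_consumption)
        occ = sim.state.geno.copy()
        sim2 = Simulation(cfg2)
        sim2.state.geno[:] = occ
        solve_gf(sim2.state, cfg2)
        assert sim2.state.gf.mean() < base

    def test_gf_monotone_in_z_with_cells(self, tiny_config):
        sim = Simulation(tiny_config)
        sim.run(60, sample_every=None)
        profile = sim.state.gf.mean(axis=(0, 1))
        assert np.all(np.diff(profile) <= 1e-12)

    def test_nonconvergence_raises(self, tiny_config):
        cfg = dataclasses.replace(tiny_config, gf_max_sweeps=2, gf_tol=1e-14)
        sim = Simulation(dataclasses.replace(tiny_config, gf_max_sweeps=50_000))
        sim.state.gf[:] = 0.0
        with pytest.raises(RuntimeError, match="residual"):
            solve_gf(sim.state, cfg)


# ---------------------------------------------------------------------------
# cell events
# ---------------------------------------------------------------------------

class TestStep:
    def test_no_rates_no_change_except_clock(self, tiny_config):
        cfg = dataclasses.replace(tiny_config, p_max=0.0, d_max=0.0)
        sim = Simulation(cfg)
        before = sim.state.geno.copy()
        sim.step()
        assert np.array_equal(sim.state.geno, before)
        assert sim.state.clock == cfg.dt_days

    def test_certain_death_empties_lattice(self, tiny_config):
        # p_die -> d_max for any u when K_die is enormous
        cfg = dataclasses.replace(tiny_config, p_max=0.0, d_max=1.0, k_die=1e12)
        sim = Simulation(cfg)
        n0 = sim.state.n_cells
        sim.step()
        assert sim.state.n_cells == 0
        assert sim.state.deaths == n0

    def test_conservation_ledger_exact(self, tiny_config):
        sim = Simulation(tiny_config)
        n0 = sim.state.n_cells
        for _ in range(150):
            sim.step()
            st = sim.state
            assert n0 + st.births - st.deaths - st.sheddings == st.n_cells

    def test_occupancy_exclusivity(self, tiny_config):
        """No two cells share a voxel (unique live cell ids)."""
        sim = Simulation(tiny_config)
        sim.run(100, sample_every=None)
        cids = sim.state.cid[sim.state.geno >= 0]
        assert np.unique(cids).size == cids.size

    def test_homeostasis_no_trend(self):
        """Weekly population counts of calibrated neutral runs have no
        significant linear trend over a simulated year (5 seeds)."""
        import scipy.stats

        series = []
        for seed in range(5):
            cfg = SimConfig(biopsy_area_mm2=0.0576, seed=seed)  # 16x16
            sim = Simulation(cfg)
            sim.run(300, sample_every=None)  # stack-up transient
            s = sim.run(365, sample_every=7.0)
            series.append(s.total)
        mean_series = np.mean(series, axis=0)
        weeks = np.arange(mean_series.size)
        fit = scipy.stats.linregress(weeks, mean_series)
        ci = 1.96 * fit.stderr
        assert fit.slope - ci <= 0.0 <= fit.slope + ci

    def test_run_determinism(self, tiny_config, default_panel):
        a = Simulation(tiny_config, default_panel)
        b = Simulation(tiny_config, default_panel)
        sa = a.run(120)
        sb = b.run(120)
        assert np.array_equal(sa.total, sb.total)
        assert np.array_equal(a.state.geno, b.state.geno)
        assert np.array_equal(a.state.cid, b.state.cid)


# ---------------------------------------------------------------------------
# daughter placement / knock-on displacement
# ---------------------------------------------------------------------------

def build_column_state(h, lz=8):
    """A 3x3 lattice with one full column of height h at (0, 0)."""
    cfg = SimConfig(biopsy_area_mm2=0.002025, lz=lz, p_max=0.0, d_max=0.0)  # 3x3
    sim = Simulation(cfg)
    sim.state.geno[:] = -1
    sim.state.geno[0, 0, :h] = 0
    sim.state.cid[0, 0, :h] = np.arange(h)
    sim.state.cid[0, 0, h:] = -1
    return cfg, sim


class TestPlaceDaughter:
    def test_empty_above_no_displacement(self, rng):
        cfg, sim = build_column_state(h=1)
        weights = dataclasses.replace(cfg, placement_weights=(0, 0, 0, 0, 1))
        site, displaced, shed = place_daughter(sim.state, (0, 0, 0), None, rng, weights)
        assert site == (0, 0, 1) and not displaced and not shed

    @pytest.mark.parametrize("h", [1, 3, 6])
    def test_full_column_shifts_up(self, rng, h):
        """Lateral insertion into a column of height h moves all h cells up
        one position (column-shift oracle)."""
        cfg, sim = build_column_state(h=h)
        before = sim.state.cid[0, 0, :h].copy()
        lateral = dataclasses.replace(cfg, placement_weights=(0, 1, 0, 0, 0))
        # parent at (1, 0, 0): its -x neighbor is column (0, 0)
        sim.state.geno[1, 0, 0] = 0
        sim.state.cid[1, 0, 0] = 99
        site, displaced, shed = place_daughter(sim.state, (1, 0, 0), None, rng, lateral)
        assert site == (0, 0, 0) and displaced and not shed
        assert np.array_equal(sim.state.cid[0, 0, 1:h + 1], before)

    def test_shift_past_top_sheds(self, rng):
        cfg, sim = build_column_state(h=8, lz=8)  # full to the brim
        top_cid = sim.state.cid[0, 0, 7]
        lateral = dataclasses.replace(cfg, placement_weights=(0, 1, 0, 0, 0))
        sim.state.geno[1, 0, 0] = 0
        sim.state.cid[1, 0, 0] = 99
        site, displaced, shed = place_daughter(sim.state, (1, 0, 0), None, rng, lateral)
        assert shed and displaced
        assert top_cid not in sim.state.cid[0, 0, :]

    def test_shift_stops_at_first_gap(self, rng):
        cfg, sim = build_column_state(h=6, lz=8)
        sim.state.geno[0, 0, 3] = -1  # poke a gap at z=3
        above_gap = sim.state.cid[0, 0, 4:6].copy()
        lateral = dataclasses.replace(cfg, placement_weights=(0, 1, 0, 0, 0))
        sim.state.geno[1, 0, 0] = 0
        sim.state.cid[1, 0, 0] = 99
        place_daughter(sim.state, (1, 0, 0), None, rng, lateral)
        # cells above the gap did not move
        assert np.array_equal(sim.state.cid[0, 0, 4:6], above_gap)
        assert sim.state.geno[0, 0, 3] >= 0  # gap absorbed the shift

    def test_periodic_wrap(self, rng):
        cfg, sim = build_column_state(h=1)
        plus_x = dataclasses.replace(cfg, placement_weights=(1, 0, 0, 0, 0))
        sim.state.geno[2, 0, 0] = 0
        sim.state.cid[2, 0, 0] = 50
        site, displaced, shed = place_daughter(sim.state, (2, 0, 0), None, rng, plus_x)
        assert site == (0, 0, 0) and displaced  # wrapped to the opposite face


# ---------------------------------------------------------------------------
# wounding
# ---------------------------------------------------------------------------

class TestWound:
    def test_wound_quarter_recovers(self):
        """Removing a quadrant of the tissue heals back to within 5% of the
        pre-wound population (GF surges where consumption stopped)."""
        recovered = []
        for seed in range(3):
            cfg = SimConfig(biopsy_area_mm2=0.0324, seed=seed)  # 12x12
            sim = Simulation(cfg)
            sim.run(400, sample_every=None)
            pre = sim.run(60, sample_every=7.0).total.mean()
            sim.wound((slice(0, 6), slice(0, 6), slice(None)))
            sim.run(250, sample_every=None)
            post = sim.run(60, sample_every=7.0).total.mean()
            recovered.append(abs(post - pre) / pre)
        assert np.mean(recovered) < 0.05

    def test_empty_wound_is_noop(self, tiny_config):
        a, b = Simulation(tiny_config), Simulation(tiny_config)
        b.wound((slice(0, 0), slice(None), slice(None)))
        sa, sb = a.run(60), b.run(60)
        assert np.array_equal(sa.total, sb.total)
        assert np.array_equal(a.state.geno, b.state.geno)

    def test_near_total_wound_recovers(self):
        cfg = SimConfig(biopsy_area_mm2=0.0324, seed=1)
        sim = Simulation(cfg)
        sim.run(350, sample_every=None)
        pre = sim.state.n_cells
        # keep only one basal edge row
        sim.wound((slice(1, None), slice(None), slice(None)))
        sim.wound((slice(0, 1), slice(None), slice(1, None)))
        assert sim.state.n_cells < 0.1 * pre
        sim.run(900, sample_every=None)
        assert sim.state.n_cells > 0.8 * pre


# ---------------------------------------------------------------------------
# lineage tracking
# ---------------------------------------------------------------------------

class TestLineages:
    def test_immortal_cells_survive_forever(self, tiny_config):
        cfg = dataclasses.replace(tiny_config, p_max=0.0, d_max=0.0)
        sim = Simulation(cfg)
        surv = track_lineages(sim, weeks=4)
        assert np.all(surv.surviving_fraction == 1.0)
        assert surv.half_life_weeks == math.inf

    def test_pure_death_half_life_matches_markov_oracle(self, tiny_config):
        """No division, death rate r: lineages are single cells dying at
        rate r, so the half-life is ln2 / r."""
        r = 0.1  # per day
        cfg = dataclasses.replace(tiny_config, p_max=0.0, d_max=r, k_die=1e12,
                                  biopsy_area_mm2=0.09)
        sim = Simulation(cfg)
        surv = track_lineages(sim, weeks=6)
        # discrete-time daily survival: (1 - r)^days
        expected_half_life_weeks = math.log(2) / (-math.log(1 - r)) / 7.0
        lo, hi = surv.half_life_ci
        assert lo <= expected_half_life_weeks <= hi

    def test_domain_invariance_of_half_life(self):
        """Basal half-life estimates agree across domain sizes (CIs overlap)."""
        results = []
        for area in (0.09, 0.25):
            sim = Simulation(SimConfig(biopsy_area_mm2=area, seed=21))
            sim.run(60, sample_every=None)
            results.append(track_lineages(sim, weeks=26))
        (lo_a, hi_a), (lo_b, hi_b) = results[0].half_life_ci, results[1].half_life_ci
        assert max(lo_a, lo_b) <= min(hi_a, hi_b)


class TestSnapshot:
    def test_lattice_dump_round_trip(self, tiny_config, tmp_path):
        import gzip
        import pandas as pd

        sim = Simulation(tiny_config)
        sim.run(30, sample_every=None)
        path = tmp_path / "lattice.tsv.gz"
        sim.dump_lattice(path)
        with gzip.open(path, "rt") as fh:
            df = pd.read_csv(fh, sep="\t")
        assert len(df) == sim.state.n_cells
        occ = np.zeros_like(sim.state.geno) - 1
        occ[df.x, df.y, df.z] = df.genotype_id
        assert np.array_equal(occ, sim.state.geno)
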