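"""The 3D hybrid cellular automaton of homeostatic epidermis.

Cells (keratinocytes) live on a 3D lattice of 15 um voxels: ``Lx x Ly``
columns matching a biopsy area, ``Lz`` layers from the basal layer (z=0) to
the shedding boundary at the top (cells pushed past z = Lz-1 leave for the
stratum corneum).  A single diffusible growth factor, sourced at the basal
layer (a fibroblast/dermis stand-in, Dirichlet boundary u = s0 at z=0),
diffuses upward while being consumed by occupied voxels and decaying, and
its quasi-steady gradient drives all cell decisions:

* division probability per day rises with local concentration,
  ``p_div(u) = p_max * u / (u + K_div)`` — so mitosis concentrates in the
  basal niche;
* death probability per day falls with concentration,
  ``p_die(u) = d_max * K_die / (u + K_die)`` — so cells climbing away from
  the source face an ever-increasing chance of death.

A dividing cell places its daughter in one of five candidate sites (four
lateral neighbors, periodic in x/y, or directly above).  If the site is
occupied, the occupant and every cell in the column above it up to the
first gap shift up one position (knock-on displacement); a cell shifted
past the top is shed.  Division is the only way cells move.  The balance
of basal division, upward displacement and GF-starved death yields an
emergent homeostatic epidermis with constant density and turnover.

Default response parameters are calibrated so a neutral run reproduces a
basal loss/replacement rate of 0.51 per week and a total density of about
120,000 cells per mm^2 (see :mod:`epidermis_evo.driver`).
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
import pandas as pd

from .genome import GenePanel, Genotype, MutationEvent, draw_mutation

__all__ = [
    "SimConfig",
    "SimState",
    "PopulationSeries",
    "Simulation",
    "init_tissue",
    "solve_gf",
    "step",
    "place_daughter",
    "wound",
    "track_lineages",
    "LineageSurvival",
]


@dataclasses.dataclass
class SimConfig:
    """Geometry, growth-factor and response parameters of the automaton.

    Lattice dimensions are derived from ``biopsy_area_mm2`` and
    ``cell_size_um`` (Lx = Ly = floor(sqrt(area)/cell_size)); the actual
    simulated area ``area_mm2`` can therefore differ from the request by up
    to one voxel row.  All rates are per day; the GF parameters are in
    voxel units (dx = 1 cell).
    """

    biopsy_area_mm2: float = 0.25
    cell_size_um: float = 15.0
    lz: int = 30
    dt_days: float = 1.0
    duration_days: float = 365.0
    # growth factor (voxel units, dx = 1)
    gf_diffusion: float = 1.0
    gf_consumption: float = 0.2
    gf_decay: float = 0.05
    gf_source: float = 1.0
    gf_tol: float = 1e-5
    gf_max_sweeps: int = 50_000
    gf_every: int = 1
    # division/death responses (per day); defaults are the calibrated
    # neutral parameterization (0.51/week basal loss, ~120k cells/mm^2)
    p_max: float = 0.1425
    k_div: float = 0.5
    d_max: float = 0.6
    k_die: float = 5.0e-7
    placement_weights: tuple[float, float, float, float, float] = (0.2, 0.2, 0.2, 0.2, 0.2)
    uv_basal_only: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.biopsy_area_mm2 <= 0 or self.cell_size_um <= 0 or self.lz <= 0:
            raise ValueError("nonpositive lattice dimensions")
        for name in ("gf_diffusion", "gf_consumption", "gf_decay", "gf_source",
                     "p_max", "k_div", "d_max", "k_die", "dt_days"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        w = np.asarray(self.placement_weights, dtype=float)
        if w.shape != (5,) or w.sum() <= 0 or (w < 0).any():
            raise ValueError("placement_weights must be 5 nonnegative weights")

    @property
    def lx(self) -> int:
        return max(1, math.floor(math.sqrt(self.biopsy_area_mm2) / (self.cell_size_um * 1e-3)))

    @property
    def ly(self) -> int:
        return self.lx

    @property
    def area_mm2(self) -> float:
        """Actual simulated area implied by the integer lattice."""
        return self.lx * self.ly * (self.cell_size_um * 1e-3) ** 2


@dataclasses.dataclass
class PopulationSeries:
    """Sampled population counts: time (days), total, basal, per driver class."""

    time: np.ndarray
    total: np.ndarray
    basal: np.ndarray
    n_notch1: np.ndarray
    n_tp53: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"day": self.time, "total": self.total, "basal": self.basal,
                             "n_notch1": self.n_notch1, "n_tp53": self.n_tp53})


class SimState:
    """Lattice state: per-voxel genotype/birth/label/cell-id, GF field, clock,
    and the cumulative event ledger (births, deaths, sheddings)."""

    def __init__(self, config: SimConfig):
        shape = (config.lx, config.ly, config.lz)
        self.geno = np.full(shape, -1, dtype=np.int32)       # genotype id, -1 = empty
        self.birth = np.zeros(shape, dtype=np.float64)       # cell birth day
        self.label = np.full(shape, -1, dtype=np.int32)      # lineage label
        self.cid = np.full(shape, -1, dtype=np.int64)        # unique cell id
        self.gf = np.zeros(shape, dtype=np.float64)
        self.clock = 0.0
        self.births = 0
        self.deaths = 0
        self.sheddings = 0
        self.basal_losses = 0  # basal cells displaced upward or killed

    @property
    def occupied(self) -> np.ndarray:
        return self.geno >= 0

    @property
    def n_cells(self) -> int:
        return int((self.geno >= 0).sum())

    @property
    def n_basal(self) -> int:
        return int((self.geno[:, :, 0] >= 0).sum())


class Simulation:
    """Owner of the automaton state, the genotype registry and RNG streams.

    Randomness is split into independent streams per concern — tissue
    events, mutation draws, UV kills, sequencing — all derived from the
    master seed, so e.g. re-drawing the sequencing noise cannot perturb the
    tissue trajectory.
    """

    def __init__(self, config: SimConfig, panel: GenePanel | None = None):
        self.config = config
        self.panel = panel
        ss = np.random.SeedSequence(config.seed)
        tissue_ss, mut_ss, uv_ss, seq_ss = ss.spawn(4)
        self.rng_tissue = np.random.default_rng(tissue_ss)
        self.rng_mutation = np.random.default_rng(mut_ss)
        self.rng_uv = np.random.default_rng(uv_ss)
        self.rng_sequencing = np.random.default_rng(seq_ss)
        self.state = SimState(config)
        founder = Genotype(0, None, ())
        self.genotypes: list[Genotype] = [founder]
        self.flag_notch1: list[bool] = [False]
        self.flag_tp53: list[bool] = [False]
        self.mutations: list[MutationEvent] = []
        self._next_cid = 0
        self._next_label = 0
        self._expected_rates = panel.expected_mutations_per_division if panel is not None else None
        self._driver_class = panel.driver_class_of() if panel is not None else {}
        self._step_counter = 0
        self._init_basal_layer()
        solve_gf(self.state, config)

    # -- initialization -------------------------------------------------------

    def _init_basal_layer(self) -> None:
        st = self.state
        lx, ly = self.config.lx, self.config.ly
        st.geno[:, :, 0] = 0
        st.birth[:, :, 0] = 0.0
        n = lx * ly
        st.cid[:, :, 0] = np.arange(n, dtype=np.int64).reshape(lx, ly)
        self._next_cid = n

    # -- bookkeeping ----------------------------------------------------------

    def add_genotype(self, parent: Genotype, events: Sequence[MutationEvent]) -> int:
        g = Genotype(len(self.genotypes), parent, events, self._driver_class)
        self.genotypes.append(g)
        self.flag_notch1.append(g.has_notch1)
        self.flag_tp53.append(g.has_tp53)
        self.mutations.extend(events)
        return g.id

    def implant_clone(self, driver_class: str, region: tuple[slice, slice] | None = None,
                      gene: str | None = None) -> int:
        """Seed a driver clone: give every basal cell in ``region`` a genotype
        carrying one mutation of ``driver_class`` (experiment setup helper)."""
        if self.panel is None:
            raise ValueError("implant_clone requires a gene panel")
        if gene is None:
            matches = self.panel.table.gene[self.panel.table.driver_class == driver_class]
            if len(matches) == 0:
                raise ValueError(f"panel has no {driver_class} gene")
            gene = str(matches.iloc[0])
        gidx = self.panel.gene_index(gene)
        ev = draw_mutation(self.panel, gidx, time=self.state.clock, rng=self.rng_mutation,
                           mut_id=len(self.mutations), parent_lineage=0)
        gid = self.add_genotype(self.genotypes[0], [ev])
        region = region or (slice(None), slice(None))
        sel = self.state.geno[region[0], region[1], 0] >= 0
        block = self.state.geno[region[0], region[1], 0]
        block[sel] = gid
        self.state.geno[region[0], region[1], 0] = block
        return gid

    def label_basal_cells(self) -> int:
        """Give every current basal cell a unique lineage label (inherited by
        all its descendants); returns the number of labeled lineages."""
        st = self.state
        st.label[:] = -1
        basal = st.geno[:, :, 0] >= 0
        n = int(basal.sum())
        lab = np.full(basal.shape, -1, dtype=np.int32)
        lab[basal] = np.arange(self._next_label, self._next_label + n, dtype=np.int32)
        st.label[:, :, 0] = lab
        self._next_label += n
        return n

    def surviving_basal_lineages(self) -> int:
        basal_occupied = self.state.geno[:, :, 0] >= 0
        lab = self.state.label[:, :, 0][basal_occupied]
        return int(np.unique(lab[lab >= 0]).size)

    def driver_counts(self) -> tuple[int, int]:
        occ = self.state.geno[self.state.geno >= 0]
        if occ.size == 0:
            return 0, 0
        n1 = np.asarray(self.flag_notch1, dtype=bool)
        p53 = np.asarray(self.flag_tp53, dtype=bool)
        return int(n1[occ].sum()), int(p53[occ].sum())

    def mutation_cell_counts(self) -> dict[int, int]:
        """Cells carrying each mutation at the current instant (for VAFs)."""
        occ = self.state.geno[self.state.geno >= 0]
        counts = np.bincount(occ, minlength=len(self.genotypes))
        out: dict[int, int] = {}
        for gid, c in enumerate(counts):
            if c == 0:
                continue
            node: Genotype | None = self.genotypes[gid]
            while node is not None:
                for ev in node.own_events:
                    out[ev.id] = out.get(ev.id, 0) + int(c)
                node = node.parent
        return out

    # -- main loop ------------------------------------------------------------

    def step(self, selection=None) -> None:
        step(self.state, self.config, selection, self.rng_tissue, sim=self)

    def run(self, days: float, selection=None, sample_every: float | None = 7.0,
            sun_schedule=None, log_progress: bool = False) -> PopulationSeries:
        """Advance the automaton ``days`` days, applying UV kill on sun days
        (if a schedule and selection with theta_s > 0 are given) and sampling
        the population every ``sample_every`` days.  ``log_progress`` emits a
        line to stderr per simulated year."""
        import sys

        from .selection import apply_uv_day  # local import to avoid a cycle

        n_steps = int(round(days / self.config.dt_days))
        times, totals, basals, n1s, p53s = [], [], [], [], []

        def sample() -> None:
            n1, p53 = self.driver_counts()
            times.append(self.state.clock)
            totals.append(self.state.n_cells)
            basals.append(self.state.n_basal)
            n1s.append(n1)
            p53s.append(p53)

        if sample_every is not None:
            sample()
        next_sample = (self.state.clock + sample_every) if sample_every is not None else None
        next_year = (self.state.clock // 365.0 + 1) * 365.0
        for _ in range(n_steps):
            self.step(selection)
            if log_progress and self.state.clock >= next_year - 1e-9:
                print(f"[epidermis-evo] year {self.state.clock / 365.0:.1f}: "
                      f"{self.state.n_cells} cells", file=sys.stderr)
                next_year += 365.0
            if sun_schedule is not None and selection is not None and selection.theta_s > 0:
                day_of_year = int(self.state.clock - self.config.dt_days) % 365 + 1
                if sun_schedule.is_sun_day(day_of_year):
                    apply_uv_day(self, selection.theta_s)
            if next_sample is not None and self.state.clock >= next_sample - 1e-9:
                sample()
                next_sample += sample_every
        return PopulationSeries(np.asarray(times), np.asarray(totals), np.asarray(basals),
                                np.asarray(n1s), np.asarray(p53s))

    def wound(self, region: tuple[slice, slice, slice]) -> None:
        wound(self.state, region)

    def dump_lattice(self, path) -> None:
        """Write an occupancy snapshot as gzipped TSV (x, y, z, genotype_id)
        for external visualization."""
        import gzip

        occ = np.argwhere(self.state.geno >= 0)
        gids = self.state.geno[occ[:, 0], occ[:, 1], occ[:, 2]]
        with gzip.open(path, "wt") as fh:
            fh.write("x\ty\tz\tgenotype_id\n")
            for (x, y, z), g in zip(occ, gids):
                fh.write(f"{x}\t{y}\t{z}\t{g}\n")


def init_tissue(config: SimConfig, panel: GenePanel | None = None,
                rng: np.random.Generator | None = None) -> Simulation:
    """Create a simulation: basal layer fully occupied by mutation-free
    founder cells, GF field solved to steady state, clock at zero.

    ``rng`` is accepted for signature compatibility; all randomness is
    derived from ``config.seed`` via per-concern streams.
    """
    return Simulation(config, panel)


# ---------------------------------------------------------------------------
# growth-factor field
# ---------------------------------------------------------------------------

def solve_gf(state: SimState, config: SimConfig) -> SimState:
    """Relax the GF field to quasi-steady state (Jacobi iteration).

    Steady state of D*laplace(u) - (decay + consumption*occupied)*u = 0 with
    u = s0 fixed on the basal plane (Dirichlet), periodic lateral faces and
    a no-flux top (the stratum corneum neither supplies nor drains GF; with
    no cells and no decay the field relaxes to the uniform value s0, and
    with decay alone the vertical profile is the classic cosh solution of a
    diffusion-decay boundary-value problem).  Iterates until the largest
    update, relative to the source amplitude, falls below ``gf_tol``;
    raises if ``gf_max_sweeps`` is exceeded.
    """
    u = state.gf
    occ = state.occupied
    D = config.gf_diffusion
    sink = config.gf_decay + config.gf_consumption * occ
    denom = 6.0 * D + sink
    s0 = config.gf_source
    u[:, :, 0] = s0
    tol = config.gf_tol * max(s0, 1e-300)
    for sweep in range(config.gf_max_sweeps):
        lat = (np.roll(u, 1, axis=0) + np.roll(u, -1, axis=0)
               + np.roll(u, 1, axis=1) + np.roll(u, -1, axis=1))
        up = np.empty_like(u)
        up[:, :, :-1] = u[:, :, 1:]
        up[:, :, -1] = u[:, :, -1]           # no-flux top: ghost mirrors the top layer
        down = np.zeros_like(u)
        down[:, :, 1:] = u[:, :, :-1]
        unew = D * (lat + up + down) / denom
        unew[:, :, 0] = s0
        delta = np.abs(unew - u).max()
        state.gf = u = unew
        if delta < tol:
            return state
    raise RuntimeError(f"GF relaxation did not converge: residual {delta:.3e} "
                       f"after {config.gf_max_sweeps} sweeps (tol {tol:.3e})")


# ---------------------------------------------------------------------------
# daughter placement / knock-on displacement
# ---------------------------------------------------------------------------

_LATERAL = ((1, 0), (-1, 0), (0, 1), (0, -1))


def _insert_with_shift(state: SimState, x: int, y: int, z: int) -> bool:
    """Make room at (x, y, z): shift the occupant and the cells above it up
    to the first gap one position upward; returns True if a cell was shed
    past the top."""
    lz = state.geno.shape[2]
    col = state.geno[x, y, z:]
    gaps = np.nonzero(col < 0)[0]
    if gaps.size:
        ze = z + int(gaps[0])
        shed = False
    else:
        ze = lz - 1
        shed = True
        state.geno[x, y, ze] = -1  # top cell leaves for the stratum corneum
    for arr in (state.geno, state.birth, state.label, state.cid):
        arr[x, y, z + 1:ze + 1] = arr[x, y, z:ze].copy()
    state.geno[x, y, z] = -1
    state.label[x, y, z] = -1
    state.cid[x, y, z] = -1
    return shed


def place_daughter(state: SimState, parent_site: tuple[int, int, int],
                   selection, rng: np.random.Generator,
                   config: SimConfig, flag_notch1: Sequence[bool] | None = None):
    """Choose and prepare a site for a daughter of the cell at parent_site.

    The target is drawn among the four lateral neighbors (periodic) and the
    site directly above, with ``config.placement_weights``.  An occupied
    target whose occupant carries a NOTCH1-class mutation may veto the
    displacement with probability f0; on veto the draw retries among the
    remaining candidates, and if every candidate is vetoed the division is
    aborted.  Returns ``(site, displaced, shed)`` or ``None`` on abort;
    a target directly above the top boundary means the daughter is shed at
    birth (``site`` is None, ``shed`` True).
    """
    from .selection import notch_block

    x, y, z = parent_site
    lx, ly, lz = state.geno.shape
    f0 = getattr(selection, "f0", 0.0) if selection is not None else 0.0
    weights = np.asarray(config.placement_weights, dtype=float)
    avail = [0, 1, 2, 3, 4]
    while avail:
        w = weights[avail]
        pick = avail[int(np.searchsorted(np.cumsum(w / w.sum()), rng.random(), side="right"))]
        if pick < 4:
            dx, dy = _LATERAL[pick]
            tx, ty, tz = (x + dx) % lx, (y + dy) % ly, z
        else:
            tx, ty, tz = x, y, z + 1
        if tz >= lz:
            return None, False, True  # born directly into the shedding boundary
        occupant = state.geno[tx, ty, tz]
        if (occupant >= 0 and f0 > 0.0 and flag_notch1 is not None
                and flag_notch1[occupant]):
            if notch_block(f0, rng):
                avail.remove(pick)
                continue
        displaced = occupant >= 0
        shed = False
        if displaced:
            shed = _insert_with_shift(state, tx, ty, tz)
        return (tx, ty, tz), displaced, shed
    return None  # every candidate vetoed: division aborted


# ---------------------------------------------------------------------------
# one timestep
# ---------------------------------------------------------------------------

def step(state: SimState, config: SimConfig, selection=None,
         rng: np.random.Generator | None = None, sim: Simulation | None = None) -> SimState:
    """Advance one timestep of cell events.

    The GF field is re-relaxed (every ``gf_every`` steps), then every cell
    is given, in one synchronized draw against the pre-step field, first a
    death check with p_die(u) and otherwise a division check with p_div(u).
    Deaths are applied, then divisions are processed in a fresh random
    permutation; a cell that was displaced before its turn forfeits its
    division.  The ledger (births - deaths - sheddings = change in N) is
    exact every step.
    """
    if rng is None:
        rng = sim.rng_tissue if sim is not None else np.random.default_rng(0)
    if sim is not None:
        sim._step_counter += 1
        if (sim._step_counter - 1) % max(1, config.gf_every) == 0:
            solve_gf(state, config)
    else:
        solve_gf(state, config)

    dt = config.dt_days
    u = state.gf
    occ = state.occupied
    p_die = dt * config.d_max * config.k_die / (u + config.k_die)
    p_div = dt * config.p_max * u / (u + config.k_div)
    r_die = rng.random(u.shape)
    r_div = rng.random(u.shape)
    die = occ & (r_die < p_die)
    divide = occ & ~die & (r_div < p_div)

    n_die = int(die.sum())
    if n_die:
        state.deaths += n_die
        state.basal_losses += int(die[:, :, 0].sum())
        state.geno[die] = -1
        state.label[die] = -1
        state.cid[die] = -1

    div_sites = np.argwhere(divide)
    flag_n1 = sim.flag_notch1 if sim is not None else None
    division_records: list[tuple[int, int]] = []  # (parent_genotype, daughter_cid)
    if len(div_sites):
        order = rng.permutation(len(div_sites))
        next_cid = sim._next_cid if sim is not None else int(state.cid.max()) + 1
        expected = state.cid[div_sites[:, 0], div_sites[:, 1], div_sites[:, 2]].copy()
        for i in order:
            x, y, z = (int(v) for v in div_sites[i])
            if state.geno[x, y, z] < 0 or state.cid[x, y, z] != expected[i]:
                continue  # displaced or gone before its turn
            parent_geno = int(state.geno[x, y, z])
            parent_label = int(state.label[x, y, z])
            outcome = place_daughter(state, (x, y, z), selection, rng, config, flag_n1)
            if outcome is None:
                continue  # all candidates vetoed
            site, displaced, shed = outcome
            state.births += 1
            if shed:
                state.sheddings += 1
            if site is None:
                continue  # daughter born past the top and shed immediately
            tx, ty, tz = site
            if tz == 0 and displaced:
                state.basal_losses += 1
            state.geno[tx, ty, tz] = parent_geno
            state.birth[tx, ty, tz] = state.clock + dt
            state.label[tx, ty, tz] = parent_label
            state.cid[tx, ty, tz] = next_cid
            division_records.append((parent_geno, next_cid))
            next_cid += 1
        if sim is not None:
            sim._next_cid = next_cid

    if sim is not None and sim.panel is not None and division_records:
        _apply_division_mutations(sim, division_records)

    state.clock += dt
    return state


def _apply_division_mutations(sim: Simulation, records: list[tuple[int, int]]) -> None:
    """Draw per-gene Poisson de novo counts for each division and mutate the
    (rare) daughters with at least one event."""
    lam = sim._expected_rates
    counts = sim.rng_mutation.poisson(lam, size=(len(records), lam.size))
    totals = counts.sum(axis=1)
    for j in np.nonzero(totals)[0]:
        parent_geno, daughter_cid = records[j]
        loc = np.nonzero((sim.state.cid == daughter_cid) & (sim.state.geno >= 0))
        if len(loc[0]) == 0:
            continue  # the daughter was shed within the same step
        parent = sim.genotypes[parent_geno]
        lineage_positions = set()
        node = parent
        while node is not None:
            lineage_positions.update(ev.position for ev in node.own_events)
            node = node.parent
        events = []
        for g in np.nonzero(counts[j])[0]:
            for _ in range(int(counts[j, g])):
                ev = draw_mutation(sim.panel, int(g), sim.state.clock + sim.config.dt_days,
                                   sim.rng_mutation, mut_id=len(sim.mutations) + len(events),
                                   parent_lineage=parent_geno,
                                   exclude_positions=lineage_positions)
                lineage_positions.add(ev.position)
                events.append(ev)
        gid = sim.add_genotype(parent, events)
        sim.state.geno[loc[0][0], loc[1][0], loc[2][0]] = gid


# ---------------------------------------------------------------------------
# wounding
# ---------------------------------------------------------------------------

def wound(state: SimState, region: tuple[slice, slice, slice]) -> SimState:
    """Remove every cell in a box of lattice coordinates.

    The GF concentration subsequently rises in the wound (consumption by the
    lost cells stops), which accelerates division of the survivors and heals
    the tissue.  Wounded cells are not counted as deaths in the ledger; the
    ledger tracks intrinsic dynamics only.
    """
    sel = state.geno[region] >= 0
    n = int(sel.sum())
    if n == 0:
        return state
    block = state.geno[region]
    block[sel] = -1
    state.geno[region] = block
    return state


# ---------------------------------------------------------------------------
# lineage tracking
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class LineageSurvival:
    """Weekly basal-lineage survival plus an exponential decay fit."""

    weeks: np.ndarray
    surviving_fraction: np.ndarray
    half_life_weeks: float
    half_life_ci: tuple[float, float]
    decay_rate_per_week: float

    def lost_fraction_at(self, week: float) -> float:
        return 1.0 - float(np.interp(week, self.weeks, self.surviving_fraction))


def track_lineages(sim: Simulation, weeks: int = 26, selection=None) -> LineageSurvival:
    """Label all basal cells, then track weekly the fraction of labeled
    lineages with at least one descendant still in the basal layer.

    Fits exp(-k t) to the weekly fractions by nonlinear least squares and
    reports the half-life ln(2)/k with a 95% CI from the fit covariance.
    """
    from scipy.optimize import curve_fit

    n0 = sim.label_basal_cells()
    if n0 == 0:
        raise ValueError("no basal cells to label")
    fracs = [1.0]
    for _ in range(weeks):
        sim.run(7.0, selection=selection, sample_every=None)
        fracs.append(sim.surviving_basal_lineages() / n0)
    t = np.arange(weeks + 1, dtype=float)
    y = np.asarray(fracs)
    if np.allclose(y, 1.0):
        return LineageSurvival(t, y, math.inf, (math.inf, math.inf), 0.0)

    def model(tt, k):
        return np.exp(-k * tt)

    popt, pcov = curve_fit(model, t, y, p0=[0.2], bounds=(1e-9, 10.0))
    k = float(popt[0])
    se = float(np.sqrt(pcov[0, 0]))
    lo, hi = max(k - 1.96 * se, 1e-12), k + 1.96 * se
    return LineageSurvival(t, y, math.log(2) / k,
                           (math.log(2) / hi, math.log(2) / lo), k)
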