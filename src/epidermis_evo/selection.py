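"""Driver selection mechanisms and the homeostasis-departure metric.

Two driver phenotypes act without touching division rates directly:

* NOTCH1 persistence — when a division targets a site occupied by a
  NOTCH1-mutant cell, the occupant vetoes the displacement with blocking
  probability ``f0``; the divider retries among its remaining candidate
  sites and the division is aborted if every candidate is vetoed.  NOTCH1
  mutants therefore persist longer in the basal layer than neutral cells.

* TP53 UV protection — on each sun-damage day (the yearly day set S) every
  non-TP53-mutant cell is killed independently with probability
  ``theta_s``; TP53 mutants are spared and expand into the vacated space.
  With no sun days a TP53 mutation is just another passenger.

Departure from homeostasis is summarized as
``dH = ln(mean((N_ref - N_test)^2))``, floored at ln(1) = 0 so two
identical trajectories score zero.
"""

from __future__ import annotations

import dataclasses

import numpy as np

__all__ = [
    "SelectionParams",
    "SunSchedule",
    "notch_block",
    "apply_uv_day",
    "departure_from_homeostasis",
]


@dataclasses.dataclass(frozen=True)
class SelectionParams:
    """f0: NOTCH1 blocking probability; theta_s: UV kill fraction per sun day."""

    f0: float = 0.0
    theta_s: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.f0 <= 1.0 and 0.0 <= self.theta_s <= 1.0):
            raise ValueError("f0 and theta_s must lie in [0, 1]")


class SunSchedule:
    """The yearly set S of sun-damage days (day-of-year integers in 1..365).

    ``SunSchedule.evenly(n)`` spreads n days uniformly over the year;
    ``SunSchedule.clustered(n, start)`` models a consecutive-day vacation.
    The schedule repeats every year by default.
    """

    def __init__(self, days, yearly: bool = True):
        days = sorted(set(int(d) for d in days))
        if any(d < 1 or d > 365 for d in days):
            raise ValueError("sun days must be day-of-year integers in 1..365")
        self.days = frozenset(days)
        self.yearly = yearly

    @classmethod
    def evenly(cls, n: int) -> "SunSchedule":
        if n == 0:
            return cls(())
        if not 1 <= n <= 365:
            raise ValueError("n must be in 0..365")
        return cls(np.unique(np.round(np.linspace(1, 365, n, endpoint=True)).astype(int)))

    @classmethod
    def clustered(cls, n: int, start: int = 150) -> "SunSchedule":
        return cls(((start - 1 + i) % 365) + 1 for i in range(n))

    @classmethod
    def from_config(cls, value) -> "SunSchedule":
        """Parse the config dialect: a list of days or the string 'evenly:N'
        or 'clustered:N[:start]'."""
        if isinstance(value, SunSchedule):
            return value
        if isinstance(value, str):
            parts = value.split(":")
            if parts[0] == "evenly":
                return cls.evenly(int(parts[1]))
            if parts[0] == "clustered":
                start = int(parts[2]) if len(parts) > 2 else 150
                return cls.clustered(int(parts[1]), start)
            raise ValueError(f"unrecognized sun_days spec {value!r}")
        return cls(value)

    def is_sun_day(self, day_of_year: int) -> bool:
        return int(day_of_year) in self.days

    def __len__(self) -> int:
        return len(self.days)


def notch_block(f0: float, rng: np.random.Generator) -> bool:
    """Does a NOTCH1-mutant occupant veto its displacement? True w.p. f0.

    Callers must invoke this only when the displacement targets an occupied
    site whose occupant carries a NOTCH1-class mutation; non-mutant
    occupants never veto (and, for f0 = 0, no randomness is consumed by the
    engine, preserving bitwise equality with the neutral trajectory).
    """
    return bool(rng.random() < f0)


def apply_uv_day(sim, theta_s: float, basal_only: bool | None = None):
    """Apply one sun-damage day: kill each non-TP53-mutant cell with
    probability theta_s (TP53 mutants get a full reprieve).

    Kills draw from the simulation's dedicated UV stream and are counted as
    deaths in the event ledger.  ``basal_only`` restricts the kill to the
    basal layer (defaults to the config flag).
    """
    if not 0.0 <= theta_s <= 1.0:
        raise ValueError("theta_s must lie in [0, 1]")
    state = sim.state
    if theta_s == 0.0:
        return state
    if basal_only is None:
        basal_only = sim.config.uv_basal_only
    occ = state.geno >= 0
    if basal_only:
        mask = np.zeros_like(occ)
        mask[:, :, 0] = occ[:, :, 0]
        occ = mask
    p53 = np.asarray(sim.flag_tp53, dtype=bool)
    vulnerable = occ.copy()
    vulnerable[occ] = ~p53[state.geno[occ]]
    draws = sim.rng_uv.random(state.geno.shape)
    kill = vulnerable & (draws < theta_s)
    n = int(kill.sum())
    if n:
        state.deaths += n
        state.basal_losses += int(kill[:, :, 0].sum())
        state.geno[kill] = -1
    return state


def departure_from_homeostasis(reference, test) -> float:
    """dH = ln(mean squared population difference), floored at zero.

    ``reference`` and ``test`` are population series (objects with a
    ``total`` attribute, or plain arrays) sampled at identical timepoints.
    The floor (mean squared difference clamped up to 1 cell^2) makes the
    identical-series case well defined: dH = ln(1) = 0.
    """
    a = np.asarray(getattr(reference, "total", reference), dtype=float)
    b = np.asarray(getattr(test, "total", test), dtype=float)
    if a.shape != b.shape:
        raise ValueError("population series must share timepoints")
    if a.size == 0:
        raise ValueError("empty population series")
    msd = float(np.mean((a - b) ** 2))
    return float(np.log(max(msd, 1.0)))
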