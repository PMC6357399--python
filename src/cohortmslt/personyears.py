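"""Expansion of wave-level panel observations into annual person-year records.

Each observed interval of L whole years becomes L one-year exposure
records.  When the states at the interval's two ends differ, the single
state change (first-order Markov assumption: at most one transition per
interval) is placed in a year drawn uniformly from the L years.  Deaths
with a known death date are placed deterministically in the year
containing the date; unknown death timing is drawn uniformly over the
following inter-wave gap.  Intervals ending in loss to follow-up
contribute no records beyond the last observation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import DEAD, PanelDataset, PanelValidationError, STATE_LABELS


@dataclass
class PersonYearTable:
    """One record per person-year of exposure (flat numpy columns)."""

    ind: np.ndarray       # row index into the source panel's individuals
    age: np.ndarray       # integer age at the start of the year
    origin: np.ndarray    # state occupied at the start of the year
    dest: np.ndarray      # state occupied at the end of the year
    woman: np.ndarray
    rural: np.ndarray
    schooled: np.ndarray
    weight: np.ndarray    # analysis weight (constant within individual)
    cohort: str = ""

    @property
    def n(self) -> int:
        return len(self.age)

    def to_frame(self, ids=None) -> pd.DataFrame:
        df = pd.DataFrame({
            "ind": self.ind, "age": self.age,
            "origin": [STATE_LABELS[s] for s in self.origin],
            "dest": [STATE_LABELS[s] for s in self.dest],
            "woman": self.woman, "rural": self.rural, "schooled": self.schooled,
            "weight": self.weight,
        })
        if ids is not None:
            df.insert(0, "id", np.asarray(ids)[self.ind])
        return df


def _concat(parts: list[dict]) -> dict:
    keys = ("ind", "age", "origin", "dest")
    if not parts:
        return {k: np.array([], dtype=np.int64) for k in keys}
    return {k: np.concatenate([p[k] for p in parts]) for k in keys}


def expand_to_person_years(data: PanelDataset, seed: int | None = 0,
                           weights: np.ndarray | None = None) -> PersonYearTable:
    """Convert a validated panel into annual person-year transition records.

    ``weights`` are per-individual analysis weights (default 1 for all);
    individuals with weight 0 are excluded (e.g. lost-to-follow-up cases
    dropped under complete-case inverse-probability weighting).  The
    expansion is deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    n = data.n
    if weights is None:
        weights = np.ones(n)
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (n,):
        raise ValueError(f"weights must have length {n}")
    if np.any(weights < 0) or np.any(~np.isfinite(weights)):
        raise ValueError("analysis weights must be finite and nonnegative")

    offsets = np.asarray(data.wave_offsets, dtype=np.int64)
    if np.any(np.diff(offsets) <= 0):
        raise PanelValidationError("wave offsets must be strictly increasing "
                                   "(zero-length observation gaps are invalid)")
    base = data.individuals["baseline_age"].to_numpy(np.int64)
    obs = data.obs_state
    lw = data.last_wave()
    dead = data.individuals["dead"].to_numpy(bool)
    death_age = data.individuals["death_age"].to_numpy(float)
    include = weights > 0

    parts: list[dict] = []
    # --- observed wave-to-wave intervals -----------------------------------
    for k in range(len(offsets) - 1):
        m = np.nonzero(include & (lw >= k + 1))[0]
        if m.size == 0:
            continue
        L = int(offsets[k + 1] - offsets[k])
        s0 = obs[m, k].astype(np.int64)
        s1 = obs[m, k + 1].astype(np.int64)
        a0 = base[m] + offsets[k]
        t_grid = np.arange(L)[None, :]
        same = s0 == s1
        if np.any(same):
            idx = m[same]
            parts.append({
                "ind": np.repeat(idx, L),
                "age": (a0[same, None] + t_grid).ravel(),
                "origin": np.repeat(s0[same], L),
                "dest": np.repeat(s0[same], L),
            })
        diff = ~same
        if np.any(diff):
            idx = m[diff]
            T = rng.integers(0, L, size=idx.size)  # uniform transition year
            s0d, s1d = s0[diff], s1[diff]
            origin = np.where(t_grid <= T[:, None], s0d[:, None], s1d[:, None])
            dest = np.where(t_grid >= T[:, None], s1d[:, None], s0d[:, None])
            parts.append({
                "ind": np.repeat(idx, L),
                "age": (a0[diff, None] + t_grid).ravel(),
                "origin": origin.ravel(),
                "dest": dest.ravel(),
            })

    # --- terminal death segments -------------------------------------------
    m = np.nonzero(include & dead)[0]
    if m.size:
        start = offsets[lw[m]]                       # offset of last observation
        s_last = obs[m, lw[m]].astype(np.int64)
        known = np.isfinite(death_age[m])
        D = np.empty(m.size, dtype=np.int64)
        # death year containing the recorded death date
        D[known] = np.floor(death_age[m][known]).astype(np.int64) - base[m][known]
        if np.any(~known):
            at_final = lw[m][~known] == len(offsets) - 1
            if np.any(at_final):
                bad = data.individuals["id"].to_numpy()[m[~known][at_final]]
                raise PanelValidationError(
                    f"dead with unknown death date after the final wave: {bad[:10].tolist()}",
                    rows=bad.tolist())
            gap = offsets[lw[m][~known] + 1] - offsets[lw[m][~known]]
            D[~known] = start[~known] + rng.integers(0, gap)  # uniform placement
        if np.any(D < start):
            bad = data.individuals["id"].to_numpy()[m[D < start]]
            raise PanelValidationError(
                f"death date precedes the last observation: {bad[:10].tolist()}",
                rows=bad.tolist())
        counts = D - start + 1
        rep = np.repeat(np.arange(m.size), counts)
        pos = np.arange(counts.sum()) - np.repeat(np.cumsum(counts) - counts, counts)
        origin = s_last[rep]
        dest = np.where(pos == counts[rep] - 1, DEAD, origin)
        parts.append({
            "ind": m[rep],
            "age": base[m][rep] + start[rep] + pos,
            "origin": origin,
            "dest": dest,
        })

    cols = _concat(parts)
    ind = cols["ind"]
    ind_frame = data.individuals
    return PersonYearTable(
        ind=ind,
        age=cols["age"].astype(np.int16),
        origin=cols["origin"].astype(np.int8),
        dest=cols["dest"].astype(np.int8),
        woman=ind_frame["woman"].to_numpy(np.int8)[ind],
        rural=ind_frame["rural"].to_numpy(np.int8)[ind],
        schooled=ind_frame["schooled"].to_numpy(np.int8)[ind],
        weight=weights[ind],
        cohort=data.cohort,
    )


def observed_exposure_years(data: PanelDataset,
                            weights: np.ndarray | None = None) -> tuple[int, int]:
    """Independent tally of whole person-years under observation, for the
    conservation check: wave-to-wave years plus terminal years to death."""
    offsets = np.asarray(data.wave_offsets, dtype=np.int64)
    base = data.individuals["baseline_age"].to_numpy(np.int64)
    lw = data.last_wave()
    include = np.ones(data.n, bool) if weights is None else np.asarray(weights) > 0
    years = offsets[lw[include]].sum()
    dead = data.individuals["dead"].to_numpy(bool) & include
    death_age = data.individuals["death_age"].to_numpy(float)
    known = dead & np.isfinite(death_age)
    years += int((np.floor(death_age[known]) - base[known]
                  - offsets[lw[known]] + 1).sum())
    return int(years), int(dead.sum() - known.sum())  # (known years, deaths w/ random year)
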