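"""Domain types and CSV I/O for longitudinal disability panels.

The analysis operates on a three-state process — nondisabled, disabled
(Katz ADL definition), dead — observed at a small number of survey waves.
This module defines the disability-state coding from the six Katz ADL
items, the covariate profile (sex, urban/rural residence, formal
schooling), and a validated long-format CSV schema with one row per
individual-wave.
"""

from __future__ import annotations


from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

# Disability states. Dead is absorbing in all downstream machinery.
NONDISABLED: int = 0
DISABLED: int = 1
DEAD: int = 2

STATE_LABELS = {NONDISABLED: "nondisabled", DISABLED: "disabled", DEAD: "dead"}
STATE_CODES = {v: k for k, v in STATE_LABELS.items()}

# Katz ADL items. The first five are "essential activities"; continence is
# coded separately (continent / incontinent).
ADL_ACTIVITIES = ("bathing", "transferring", "dressing", "eating", "toileting")
INDEPENDENT = "independent"
NEEDS_ASSISTANCE = "needs_assistance"
CONTINENT = "continent"
INCONTINENT = "incontinent"

DAYS_PER_YEAR = 365.25


class PanelValidationError(ValueError):
    """Raised when a panel violates the schema or its invariants.

    ``rows`` carries the offending row indices / ids where applicable.
    """

    def __init__(self, message: str, rows: Sequence | None = None):
        super().__init__(message)
        self.rows = list(rows) if rows is not None else []


class MissingADLItemError(PanelValidationError):
    """An ADL item is missing and no precoded state is available."""


@dataclass(frozen=True)
class ADLResponse:
    """Responses to the six Katz ADL items for one interview."""

    bathing: str
    transferring: str
    dressing: str
    eating: str
    toileting: str
    continence: str

    def items(self) -> tuple[str, ...]:
        return (self.bathing, self.transferring, self.dressing,
                self.eating, self.toileting, self.continence)


def derive_disability_state(items: ADLResponse) -> int:
    """Code the disability state from the six Katz ADL items.

    Disabled means needing personal assistance in one or more of the five
    essential activities (bathing, transferring, dressing, eating,
    toileting) *or* being incontinent; otherwise nondisabled.  Missing
    items are an error — no silent imputation.
    """
    for name in ADL_ACTIVITIES:
        value = getattr(items, name)
        if value not in (INDEPENDENT, NEEDS_ASSISTANCE):
            raise MissingADLItemError(f"ADL item {name!r} is missing or invalid: {value!r}")
    if items.continence not in (CONTINENT, INCONTINENT):
        raise MissingADLItemError(f"ADL item 'continence' is missing or invalid: {items.continence!r}")
    needs_help = any(getattr(items, name) == NEEDS_ASSISTANCE for name in ADL_ACTIVITIES)
    if needs_help or items.continence == INCONTINENT:
        return DISABLED
    return NONDISABLED


@dataclass(frozen=True)
class CovariateProfile:
    """Binary sociodemographic profile: sex, residence, formal schooling."""

    sex: str        # "man" / "woman"
    residence: str  # "urban" / "rural"
    schooling: str  # "some" (1+ year formal schooling) / "none"

    def __post_init__(self):
        if self.sex not in ("man", "woman"):
            raise ValueError(f"sex must be 'man' or 'woman', got {self.sex!r}")
        if self.residence not in ("urban", "rural"):
            raise ValueError(f"residence must be 'urban' or 'rural', got {self.residence!r}")
        if self.schooling not in ("some", "none"):
            raise ValueError(f"schooling must be 'some' or 'none', got {self.schooling!r}")

    @property
    def woman(self) -> int:
        return int(self.sex == "woman")

    @property
    def rural(self) -> int:
        return int(self.residence == "rural")

    @property
    def schooled(self) -> int:
        return int(self.schooling == "some")

    def indicators(self) -> tuple[int, int, int]:
        return (self.woman, self.rural, self.schooled)

    @property
    def index(self) -> int:
        """Profile index 0..7: woman*4 + rural*2 + schooled."""
        return self.woman * 4 + self.rural * 2 + self.schooled

    @classmethod
    def from_index(cls, idx: int) -> "CovariateProfile":
        if not 0 <= idx <= 7:
            raise ValueError(f"profile index must be in 0..7, got {idx}")
        woman, rural, schooled = (idx >> 2) & 1, (idx >> 1) & 1, idx & 1
        return cls(sex="woman" if woman else "man",
                   residence="rural" if rural else "urban",
                   schooling="some" if schooled else "none")


ALL_PROFILES: tuple[CovariateProfile, ...] = tuple(
    CovariateProfile.from_index(i) for i in range(8)
)

# Decode tables: profile index -> (woman, rural, schooled).
PROFILE_WOMAN = np.array([(i >> 2) & 1 for i in range(8)], dtype=np.int8)
PROFILE_RURAL = np.array([(i >> 1) & 1 for i in range(8)], dtype=np.int8)
PROFILE_SCHOOLED = np.array([i & 1 for i in range(8)], dtype=np.int8)


@dataclass
class IndividualRecord:
    """Record-level view of one panel member (convenience API)."""

    id: str
    birth_cohort_label: str
    baseline_age: int
    profile: CovariateProfile
    wave_observations: list[tuple[pd.Timestamp, int, int]]  # (date, age, state)
    death_date: pd.Timestamp | None
    lost_to_followup: bool
    sampling_weight: float
    auxiliary_covariates: dict


# Columns of the per-individual frame inside PanelDataset.
_IND_COLUMNS = ("id", "baseline_age", "woman", "rural", "schooled", "dead",
                "death_age", "lost", "sampling_weight", "baseline_date")


@dataclass
class PanelDataset:
    """A validated panel: individuals x waves with states and covariates.

    ``individuals`` holds one row per person (time-invariant fields, with
    sex/residence/schooling stored as 0/1 indicators ``woman``, ``rural``,
    ``schooled``).  ``obs_state`` is an (n, n_waves) int8 matrix of
    observed disability states, -1 where the wave was not observed
    (after death or loss to follow-up).  Ages at waves are implied:
    ``baseline_age + wave_offsets[k]``.
    """

    individuals: pd.DataFrame
    obs_state: np.ndarray
    wave_offsets: np.ndarray
    cohort: str = ""
    age_window: tuple[int, int] | None = None
    aux_columns: tuple[str, ...] = ()

    @property
    def n(self) -> int:
        return len(self.individuals)

    @property
    def n_waves(self) -> int:
        return len(self.wave_offsets)

    @property
    def baseline_state(self) -> np.ndarray:
        return self.obs_state[:, 0]

    @property
    def profile_index(self) -> np.ndarray:
        ind = self.individuals
        return (ind["woman"].to_numpy() * 4 + ind["rural"].to_numpy() * 2
                + ind["schooled"].to_numpy()).astype(np.int8)

    def obs_age(self) -> np.ndarray:
        """(n, n_waves) ages at waves; meaningful only where obs_state >= 0."""
        base = self.individuals["baseline_age"].to_numpy()
        return base[:, None] + np.asarray(self.wave_offsets)[None, :]

    def last_wave(self) -> np.ndarray:
        """Index of each individual's last observed wave."""
        observed = self.obs_state >= 0
        return observed.shape[1] - 1 - np.argmax(observed[:, ::-1], axis=1)

    def subset(self, idx: np.ndarray) -> "PanelDataset":
        """Row-subset (bootstrap resampling); skips id-uniqueness checks."""
        return PanelDataset(
            individuals=self.individuals.iloc[idx].reset_index(drop=True),
            obs_state=self.obs_state[idx],
            wave_offsets=self.wave_offsets,
            cohort=self.cohort,
            age_window=self.age_window,
            aux_columns=self.aux_columns,
        )

    def equals(self, other: "PanelDataset") -> bool:
        if self.n != other.n or not np.array_equal(self.wave_offsets, other.wave_offsets):
            return False
        if not np.array_equal(self.obs_state, other.obs_state):
            return False
        a = self.individuals.reset_index(drop=True)
        b = other.individuals.reset_index(drop=True)
        if set(a.columns) != set(b.columns):
            return False
        for col in a.columns:
            x, y = a[col], b[col]
            if x.dtype.kind == "f" or y.dtype.kind == "f":
                xa, ya = x.to_numpy(float), y.to_numpy(float)
                if not np.allclose(xa, ya, equal_nan=True, rtol=0, atol=1e-9):
                    return False
            else:
                if not (x.astype(str) == y.astype(str)).all():
                    return False
        return True

    def iter_records(self) -> Iterator[IndividualRecord]:
        offsets = np.asarray(self.wave_offsets)
        for i, row in self.individuals.iterrows():
            base_date = pd.Timestamp(row["baseline_date"])
            obs = []
            for k, off in enumerate(offsets):
                s = int(self.obs_state[i, k])
                if s < 0:
                    continue
                obs.append((base_date + pd.Timedelta(days=round(off * DAYS_PER_YEAR)),
                            int(row["baseline_age"] + off), s))
            death_date = None
            if bool(row["dead"]) and np.isfinite(row["death_age"]):
                days = round((row["death_age"] - row["baseline_age"]) * DAYS_PER_YEAR)
                death_date = base_date + pd.Timedelta(days=days)
            profile = CovariateProfile.from_index(
                int(row["woman"]) * 4 + int(row["rural"]) * 2 + int(row["schooled"]))
            yield IndividualRecord(
                id=str(row["id"]), birth_cohort_label=self.cohort,
                baseline_age=int(row["baseline_age"]), profile=profile,
                wave_observations=obs, death_date=death_date,
                lost_to_followup=bool(row["lost"]),
                sampling_weight=float(row["sampling_weight"]),
                auxiliary_covariates={c: row[c] for c in self.aux_columns},
            )


def validate_panel(data: PanelDataset) -> None:
    """Check the dataset invariants; raise PanelValidationError on failure."""
    ind = data.individuals
    ids = ind["id"].astype(str)
    if ids.duplicated().any():
        dup = ids[ids.duplicated()].unique().tolist()
        raise PanelValidationError(f"duplicate individual ids: {dup[:10]}", rows=dup)
    offsets = np.asarray(data.wave_offsets)
    if len(offsets) < 1 or offsets[0] != 0 or np.any(np.diff(offsets) <= 0):
        raise PanelValidationError(
            f"wave offsets must start at 0 and be strictly increasing, got {offsets.tolist()}")
    if data.obs_state.shape != (data.n, len(offsets)):
        raise PanelValidationError("obs_state shape does not match individuals x waves")
    if np.any(data.obs_state[:, 0] < 0):
        bad = ids[data.obs_state[:, 0] < 0].tolist()
        raise PanelValidationError(f"individuals missing the baseline wave: {bad[:10]}", rows=bad)
    if np.any((data.obs_state > 1) | (data.obs_state < -1)):
        raise PanelValidationError("observed states must be nondisabled/disabled (or -1 unobserved)")
    # Observed waves must form a contiguous prefix (no re-entry after a gap).
    observed = data.obs_state >= 0
    lw = data.last_wave()
    prefix_ok = observed.sum(axis=1) == lw + 1
    if not prefix_ok.all():
        bad = ids[~prefix_ok].tolist()
        raise PanelValidationError(
            f"observation gaps (missing wave before a later observed wave): {bad[:10]}", rows=bad)
    sw = ind["sampling_weight"].to_numpy(float)
    if np.any(~np.isfinite(sw)) or np.any(sw <= 0):
        bad = ids[(~np.isfinite(sw)) | (sw <= 0)].tolist()
        raise PanelValidationError(f"non-positive sampling weights: {bad[:10]}", rows=bad)
    dead = ind["dead"].to_numpy(bool)
    lost = ind["lost"].to_numpy(bool)
    if np.any(dead & lost):
        bad = ids[dead & lost].tolist()
        raise PanelValidationError(f"individuals flagged both dead and lost: {bad[:10]}", rows=bad)
    death_age = ind["death_age"].to_numpy(float)
    base = ind["baseline_age"].to_numpy()
    has_da = np.isfinite(death_age)
    if np.any(has_da & ~dead):
        bad = ids[has_da & ~dead].tolist()
        raise PanelValidationError(f"death date present without dead flag: {bad[:10]}", rows=bad)
    # No observations after death: age at last observed wave must not exceed death age.
    last_age = base + offsets[lw]
    bad_mask = dead & has_da & (last_age > death_age)
    if np.any(bad_mask):
        bad = ids[bad_mask].tolist()
        raise PanelValidationError(
            f"observation dated after death for ids: {bad[:10]}", rows=bad)
    if data.age_window is not None:
        lo, hi = data.age_window
        out = (base < lo) | (base > hi)
        if np.any(out):
            bad = ids[out].tolist()
            raise PanelValidationError(
                f"baseline ages outside window {lo}-{hi}: {bad[:10]}", rows=bad)


# ---------------------------------------------------------------------------
# CSV schema
# ---------------------------------------------------------------------------

CSV_COLUMNS = ["id", "wave_index", "wave_date", "age",
               "bathing", "transferring", "dressing", "eating", "toileting",
               "continence", "state", "dead", "death_date", "lost",
               "sex", "residence", "schooling", "sampling_weight"]


def _offset_days(offset_years: float) -> int:
    return int(round(offset_years * DAYS_PER_YEAR))


def write_panel(data: PanelDataset, path) -> None:
    """Write the panel to the documented long-format CSV (one row per
    individual-wave).  States are written precoded (ADL item columns are
    left empty); absent death dates are empty fields, not sentinels."""
    ind = data.individuals
    offsets = np.asarray(data.wave_offsets)
    rows = []
    for i in range(data.n):
        r = ind.iloc[i]
        base_date = pd.Timestamp(r["baseline_date"])
        profile = CovariateProfile.from_index(
            int(r["woman"]) * 4 + int(r["rural"]) * 2 + int(r["schooled"]))
        if bool(r["dead"]) and np.isfinite(r["death_age"]):
            dd = (base_date + pd.Timedelta(
                days=round((r["death_age"] - r["baseline_age"]) * DAYS_PER_YEAR)))
            death_date = dd.date().isoformat()
        else:
            death_date = ""
        for k, off in enumerate(offsets):
            s = int(data.obs_state[i, k])
            if s < 0:
                continue
            rows.append({
                "id": r["id"],
                "wave_index": k,
                "wave_date": (base_date + pd.Timedelta(days=_offset_days(off))).date().isoformat(),
                "age": int(r["baseline_age"] + off),
                "bathing": "", "transferring": "", "dressing": "",
                "eating": "", "toileting": "", "continence": "",
                "state": STATE_LABELS[s],
                "dead": int(bool(r["dead"])),
                "death_date": death_date,
                "lost": int(bool(r["lost"])),
                "sex": profile.sex,
                "residence": profile.residence,
                "schooling": profile.schooling,
                "sampling_weight": repr(float(r["sampling_weight"])),
                **{f"aux_{c}": r[c] for c in data.aux_columns},
            })
    cols = CSV_COLUMNS + [f"aux_{c}" for c in data.aux_columns]
    frame = pd.DataFrame(rows, columns=cols)
    frame.to_csv(path, index=False)


def _row_state(row: pd.Series, require_items: bool) -> int:
    """Disability state for one CSV row: derive from ADL items when all six
    are present, otherwise fall back to the precoded ``state`` column."""
    item_values = [row[c] for c in ADL_ACTIVITIES] + [row["continence"]]
    n_present = sum(v != "" for v in item_values)
    if n_present == 6:
        items = ADLResponse(*(row[c] for c in ADL_ACTIVITIES), continence=row["continence"])
        derived = derive_disability_state(items)
        if row["state"] != "" and STATE_CODES.get(row["state"]) != derived:
            raise PanelValidationError(
                f"id {row['id']!r} wave {row['wave_index']}: precoded state "
                f"{row['state']!r} contradicts ADL items")
        return derived
    if n_present > 0:
        raise MissingADLItemError(
            f"id {row['id']!r} wave {row['wave_index']}: {6 - n_present} ADL item(s) missing")
    if require_items:
        raise MissingADLItemError(
            f"id {row['id']!r} wave {row['wave_index']}: ADL items required but absent")
    if row["state"] not in STATE_CODES or STATE_CODES[row["state"]] == DEAD:
        raise PanelValidationError(
            f"id {row['id']!r} wave {row['wave_index']}: no ADL items and no valid "
            f"precoded state (got {row['state']!r})")
    return STATE_CODES[row["state"]]


def read_panel(path, cohort: str = "", age_window: tuple[int, int] | None = None,
               require_items: bool = False) -> PanelDataset:
    """Read and validate a long-format panel CSV.

    Per-row disability states are derived from the six ADL items when
    present; otherwise the precoded ``state`` column is used (set
    ``require_items=True`` to forbid the fallback).
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in CSV_COLUMNS if c not in raw.columns]
    if missing:
        raise PanelValidationError(f"panel CSV missing required columns: {missing}")
    aux_cols = tuple(c[4:] for c in raw.columns if c.startswith("aux_"))
    if raw.empty:
        ind = pd.DataFrame(columns=list(_IND_COLUMNS) + list(aux_cols))
        return PanelDataset(individuals=ind, obs_state=np.zeros((0, 1), dtype=np.int8),
                            wave_offsets=np.array([0]), cohort=cohort,
                            age_window=age_window, aux_columns=aux_cols)

    raw["wave_index"] = raw["wave_index"].astype(int)
    raw["age"] = raw["age"].astype(int)
    dup = raw.duplicated(subset=["id", "wave_index"])
    if dup.any():
        bad = raw.loc[dup, "id"].unique().tolist()
        raise PanelValidationError(f"duplicate (id, wave) rows for ids: {bad[:10]}", rows=bad)

    states = raw.apply(_row_state, axis=1, args=(require_items,)).astype(np.int8)
    raw = raw.assign(_state=states)
    raw["wave_date"] = pd.to_datetime(raw["wave_date"])

    n_waves = int(raw["wave_index"].max()) + 1
    # Wave offsets: age difference to baseline, consistent across individuals.
    base_age = raw[raw["wave_index"] == 0].set_index("id")["age"]
    raw["_offset"] = raw["age"].to_numpy() - base_age.reindex(raw["id"]).to_numpy()
    offset_table = raw.groupby("wave_index")["_offset"].agg(["min", "max"])
    if (offset_table["min"] != offset_table["max"]).any():
        raise PanelValidationError("inconsistent age offsets across individuals within a wave")
    offsets = offset_table["min"].reindex(range(n_waves)).to_numpy()
    if np.isnan(offsets).any():
        raise PanelValidationError("a wave index is never observed by any individual")
    offsets = offsets.astype(int)

    ind_rows = []
    obs_state = []
    for ind_id, grp in raw.groupby("id", sort=True):
        grp = grp.sort_values("wave_index")
        if not grp["wave_date"].is_monotonic_increasing:
            raise PanelValidationError(f"wave dates not strictly increasing for id {ind_id!r}",
                                       rows=[ind_id])
        first = grp.iloc[0]
        if first["wave_index"] != 0:
            raise PanelValidationError(f"id {ind_id!r} is missing the baseline wave",
                                       rows=[ind_id])
        profile = CovariateProfile(sex=first["sex"], residence=first["residence"],
                                   schooling=first["schooling"])
        dead = bool(int(first["dead"]))
        lost = bool(int(first["lost"]))
        base_date = first["wave_date"]
        death_age = np.nan
        if first["death_date"] != "":
            dd = pd.Timestamp(first["death_date"])
            death_age = float(first["age"]) + (dd - base_date).days / DAYS_PER_YEAR
            if (grp["wave_date"] > dd).any():
                raise PanelValidationError(
                    f"observation dated after death for id {ind_id!r}", rows=[ind_id])
        row_states = np.full(n_waves, -1, dtype=np.int8)
        row_states[grp["wave_index"].to_numpy()] = grp["_state"].to_numpy()
        ind_rows.append({
            "id": str(ind_id), "baseline_age": int(first["age"]),
            "woman": profile.woman, "rural": profile.rural, "schooled": profile.schooled,
            "dead": dead, "death_age": death_age, "lost": lost,
            "sampling_weight": float(first["sampling_weight"]),
            "baseline_date": base_date,
            **{c: first[f"aux_{c}"] for c in aux_cols},
        })
        obs_state.append(row_states)

    individuals = pd.DataFrame(ind_rows)
    for c in aux_cols:  # aux covariates are binary/categorical codes
        try:
            individuals[c] = pd.to_numeric(individuals[c])
        except (ValueError, TypeError):
            pass
    data = PanelDataset(individuals=individuals, obs_state=np.vstack(obs_state),
                        wave_offsets=offsets, cohort=cohort, age_window=age_window,
                        aux_columns=aux_cols)
    validate_panel(data)
    return data
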