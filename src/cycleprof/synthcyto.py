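"""Synthetic DNA-content cytometry generator with known ground truth.

Emulates a 384-well cell-cycle screen: a DNA-selective stain emits
fluorescence proportional to DNA mass, so a 2N (G1) cell sits at one peak,
a 4N (G2/M) cell at twice that intensity, S-phase cells spread between the
two peaks as they replicate, and apoptotic (subG1) debris falls below the
2N peak.  Viability plates and dose-response plates are generated from
known 4PL curves so recovery of every downstream statistic can be tested
against the truth used to generate the data.
"""

from __future__ import annotations

import hashlib
import string
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from cycleprof.errors import MissingCompoundError, ValidationError

PHASES = ("g1", "s", "g2m", "subg1")

#: Unperturbed (DMSO vehicle) cell-cycle composition of an asynchronously
#: cycling HeLa population: >50% G1, ~10% S, ~30% G2/M, <5% subG1.
DMSO_TRUTH: "PhaseFractions"

#: Canonical 8-point final-concentration dose grid (µM), the stock serial
#: dilution series scaled by the 1/1000 plating dilution.
DEFAULT_DOSES_UM = (50.0, 12.5, 3.125, 0.781, 0.26, 0.065, 0.016, 0.004)


@dataclass(frozen=True)
class PhaseFractions:
    """One well's four-phase composition; fractions summing to 1."""

    g1: float
    s: float
    g2m: float
    subg1: float

    def __post_init__(self) -> None:
        vals = (self.g1, self.s, self.g2m, self.subg1)
        for name, v in zip(PHASES, vals):
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"fraction {name}={v} outside [0, 1]")
        total = sum(vals)
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"fractions sum to {total!r}, not 1")

    def as_array(self) -> np.ndarray:
        return np.array([self.g1, self.s, self.g2m, self.subg1], float)

    def as_percent(self) -> np.ndarray:
        return 100.0 * self.as_array()


DMSO_TRUTH = PhaseFractions(g1=0.54, s=0.10, g2m=0.31, subg1=0.05)


@dataclass(frozen=True)
class PopulationModel:
    """Stain-signal model: peak location, spread, and events per well.

    ``g1_mean`` is the 2N peak intensity (arbitrary fluorescence units);
    ``cv`` the per-peak coefficient of variation (0.03-0.08 typical for a
    plate cytometer); ``subg1_low`` the lower bound of subG1 debris as a
    fraction of the 2N peak.
    """

    g1_mean: float = 100.0
    cv: float = 0.05
    n_events: int = 5000
    subg1_low: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.g1_mean <= 0:
            raise ValidationError(f"g1_mean must be > 0, got {self.g1_mean}")
        if not (0.0 < self.cv < 0.3):
            raise ValidationError(f"cv must be in (0, 0.3), got {self.cv}")
        if self.n_events < 1:
            raise ValidationError(f"n_events must be >= 1, got {self.n_events}")
        if not (0.0 < self.subg1_low < 1.0):
            raise ValidationError(f"subg1_low must be in (0, 1), got {self.subg1_low}")


@dataclass
class WellEvents:
    """Per-cell fluorescence intensities for one well.

    ``labels`` carries the generating phase of each event when the well is
    synthetic; gating never reads it — it exists for oracle tests.
    """

    well_id: str
    intensities: np.ndarray
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, float)

    def __len__(self) -> int:
        return self.intensities.size


def _positive_normal(rng: np.random.Generator, mean: float, sd: float, n: int) -> np.ndarray:
    """Normal(mean, sd) truncated to > 0 by redrawing (negligible mass cut)."""
    out = rng.normal(mean, sd, n)
    bad = out <= 0
    while bad.any():
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = out <= 0
    return out


def simulate_well(
    fractions: PhaseFractions,
    model: PopulationModel,
    well_id: str = "A01",
    rng: np.random.Generator | None = None,
) -> WellEvents:
    """Draw one well of per-cell intensities under the DNA-mass model.

    Phase membership is multinomial(n_events, fractions).  G1 intensities are
    Normal(g1_mean, cv*g1_mean) truncated positive, G2/M Normal at twice the
    mean, S uniform between the 2N and 4N peaks with multiplicative Normal
    noise, and subG1 uniform on [subg1_low*g1_mean, g1_mean*(1 - 2 cv)].
    The same (fractions, model) pair reproduces identical events.
    """
    if rng is None:
        rng = np.random.default_rng(model.seed)
    m, cv = model.g1_mean, model.cv
    counts = rng.multinomial(model.n_events, fractions.as_array())
    n_g1, n_s, n_g2m, n_sub = (int(c) for c in counts)

    g1 = _positive_normal(rng, m, cv * m, n_g1)
    s_base = rng.uniform(m, 2.0 * m, n_s)
    s = s_base + rng.normal(0.0, 1.0, n_s) * (cv * s_base)
    bad = s <= 0
    while bad.any():  # multiplicative noise almost never drives S negative
        redraw = rng.uniform(m, 2.0 * m, int(bad.sum()))
        s[bad] = redraw + rng.normal(0.0, 1.0, int(bad.sum())) * (cv * redraw)
        bad = s <= 0
    g2m = _positive_normal(rng, 2.0 * m, cv * 2.0 * m, n_g2m)
    sub = rng.uniform(model.subg1_low * m, m * (1.0 - 2.0 * cv), n_sub)

    intensities = np.concatenate([g1, s, g2m, sub])
    labels = np.concatenate([
        np.repeat("g1", n_g1), np.repeat("s", n_s),
        np.repeat("g2m", n_g2m), np.repeat("subg1", n_sub),
    ])
    return WellEvents(well_id=well_id, intensities=intensities, labels=labels)


# ---------------------------------------------------------------------------
# plate layout


_ROW_LETTERS = string.ascii_uppercase


def well_name(row: int, col: int) -> str:
    """0-based (row, col) -> plate coordinate label, e.g. (0, 0) -> 'A01'."""
    return f"{_ROW_LETTERS[row]}{col + 1:02d}"


@dataclass(frozen=True)
class WellRole:
    role: str  # compound | dmso_control | positive_control | empty
    compound: str | None = None
    concentration_uM: float | None = None


@dataclass
class PlateMap:
    """Role assignment for every well of a rows x cols plate."""

    rows: int = 16
    cols: int = 24
    wells: dict[str, WellRole] = field(default_factory=dict)

    def __post_init__(self) -> None:
        valid = {"compound", "dmso_control", "positive_control", "empty"}
        for wid, wr in self.wells.items():
            if wr.role not in valid:
                raise ValidationError(f"well {wid}: unknown role {wr.role!r}")
        if self.wells and not self.dmso_wells():
            raise ValidationError("plate map has no dmso_control well to reference against")

    def dmso_wells(self) -> list[str]:
        return sorted(w for w, r in self.wells.items() if r.role == "dmso_control")

    def compound_wells(self) -> list[str]:
        return sorted(w for w, r in self.wells.items() if r.role == "compound")

    def positive_wells(self) -> list[str]:
        return sorted(w for w, r in self.wells.items() if r.role == "positive_control")

    def non_empty_wells(self) -> list[str]:
        return sorted(w for w, r in self.wells.items() if r.role != "empty")

    @classmethod
    def build(
        cls,
        compounds: list[str],
        n_dmso: int = 16,
        n_positive: int = 0,
        rows: int = 16,
        cols: int = 24,
        concentration_uM: float = 10.0,
    ) -> "PlateMap":
        """Fill a plate row-major: DMSO controls first, then positive
        controls, then one well per compound; the remainder left empty."""
        n_needed = n_dmso + n_positive + len(compounds)
        if n_needed > rows * cols:
            raise ValidationError(f"{n_needed} wells requested on a {rows * cols}-well plate")
        order = [well_name(r, c) for r in range(rows) for c in range(cols)]
        wells: dict[str, WellRole] = {}
        i = 0
        for _ in range(n_dmso):
            wells[order[i]] = WellRole("dmso_control")
            i += 1
        for _ in range(n_positive):
            wells[order[i]] = WellRole("positive_control")
            i += 1
        for name in compounds:
            wells[order[i]] = WellRole("compound", compound=name, concentration_uM=concentration_uM)
            i += 1
        for wid in order[i:]:
            wells[wid] = WellRole("empty")
        return cls(rows=rows, cols=cols, wells=wells)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"well_id": wid, "role": wr.role, "compound": wr.compound or "",
             "concentration_uM": "" if wr.concentration_uM is None else wr.concentration_uM}
            for wid, wr in sorted(self.wells.items())
        ]
        return pd.DataFrame(rows, columns=["well_id", "role", "compound", "concentration_uM"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, rows: int = 16, cols: int = 24) -> "PlateMap":
        df = pd.read_csv(path, dtype={"well_id": str, "role": str, "compound": str})
        wells = {}
        for rec in df.itertuples(index=False):
            conc = getattr(rec, "concentration_uM", None)
            conc = None if conc is None or pd.isna(conc) or conc == "" else float(conc)
            comp = rec.compound if isinstance(rec.compound, str) and rec.compound else None
            wells[rec.well_id] = WellRole(rec.role, compound=comp, concentration_uM=conc)
        return cls(rows=rows, cols=cols, wells=wells)


def well_seed(plate_seed: int, well_id: str) -> int:
    """Deterministic 31-bit per-well seed from (plate seed, well id).

    sha256-based so it is identical across platforms and Python runs,
    unlike the builtin ``hash``.
    """
    digest = hashlib.sha256(f"{plate_seed}|{well_id}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def simulate_plate(
    plate_map: PlateMap,
    truth: dict[str, PhaseFractions],
    model: PopulationModel,
    dmso_truth: PhaseFractions = DMSO_TRUTH,
) -> tuple[dict[str, WellEvents], pd.DataFrame]:
    """Simulate every non-empty well of a plate.

    Returns the events keyed by well id plus a ground-truth table
    (well_id, compound, true g1/s/g2m/subg1) for recovery testing.
    Per-well RNG streams derive from (model.seed, well_id) so wells are
    reproducible independent of simulation order.
    """
    for wid in plate_map.compound_wells():
        name = plate_map.wells[wid].compound
        if name not in truth:
            raise MissingCompoundError(name)
    events: dict[str, WellEvents] = {}
    records = []
    for wid in plate_map.non_empty_wells():
        wr = plate_map.wells[wid]
        if wr.role == "compound":
            frac, label = truth[wr.compound], wr.compound
        elif wr.role == "dmso_control":
            frac, label = dmso_truth, "DMSO"
        else:  # positive_control: canonical G2/M arrester with apoptosis
            frac, label = PhaseFractions(0.05, 0.05, 0.80, 0.10), "POS"
        rng = np.random.default_rng(well_seed(model.seed, wid))
        events[wid] = simulate_well(frac, model, well_id=wid, rng=rng)
        records.append({"well_id": wid, "compound": label, "role": wr.role,
                        "g1": frac.g1, "s": frac.s, "g2m": frac.g2m, "subg1": frac.subg1})
    return events, pd.DataFrame(records)


def simulate_viability_plate(
    plate_map: PlateMap,
    true_viability: dict[str, float],
    signal_mean: float = 1000.0,
    cv: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-well luminescence: reading = viability * signal_mean * (1 + N(0, cv)).

    DMSO wells have viability 1, positive controls 0; readings floored at 0.
    """
    if cv <= 0:
        raise ValidationError(f"cv must be > 0, got {cv}")
    records = []
    for wid in plate_map.non_empty_wells():
        wr = plate_map.wells[wid]
        if wr.role == "compound":
            if wr.compound not in true_viability:
                raise MissingCompoundError(wr.compound)
            v, label = true_viability[wr.compound], wr.compound
        elif wr.role == "dmso_control":
            v, label = 1.0, "DMSO"
        else:
            v, label = 0.0, "POS"
        if not (0.0 <= v <= 1.0):
            raise ValidationError(f"viability for {label!r} must be in [0, 1], got {v}")
        rng = np.random.default_rng(well_seed(seed, wid))
        reading = max(0.0, v * signal_mean * (1.0 + rng.normal(0.0, cv)))
        records.append({"well_id": wid, "role": wr.role, "compound": label, "reading": reading})
    return pd.DataFrame(records)


def simulate_dose_response(
    ec50: float,
    hill: float = 1.0,
    top: float = 100.0,
    bottom: float = 0.0,
    doses=DEFAULT_DOSES_UM,
    cv: float = 0.05,
    replicates: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Replicate responses on a dose grid from a known 4PL curve.

    Mean response is bottom + (top - bottom)/(1 + (dose/ec50)^hill) with
    multiplicative Normal(0, cv) noise (cv=0 gives the exact curve).
    """
    if ec50 <= 0:
        raise ValidationError(f"ec50 must be > 0, got {ec50}")
    doses = np.asarray(doses, float)
    if (doses <= 0).any():
        raise ValidationError("all doses must be > 0")
    rng = np.random.default_rng(seed)
    records = []
    for dose in doses:
        mu = bottom + (top - bottom) / (1.0 + (dose / ec50) ** hill)
        for rep in range(1, replicates + 1):
            noise = rng.normal(0.0, cv) if cv > 0 else 0.0
            records.append({"dose_uM": float(dose), "replicate": rep,
                            "response": mu * (1.0 + noise)})
    return pd.DataFrame(records)


#: canonical arrest archetypes a screen encounters, as target compositions
ARCHETYPES = {
    "g2m_arrest": (0.07, 0.05, 0.80, 0.08),
    "g1_arrest": (0.85, 0.05, 0.05, 0.05),
    "s_arrest": (0.30, 0.45, 0.20, 0.05),
    "apoptosis": (0.35, 0.08, 0.27, 0.30),
}


def make_screen_truth(
    n_shifted: int = 20,
    n_dmso_like: int = 40,
    n_moderate: int = 36,
    seed: int = 0,
    min_shift_pct: float = 15.0,
    dmso_truth: PhaseFractions = DMSO_TRUTH,
) -> tuple[dict[str, PhaseFractions], dict[str, float]]:
    """Ground-truth fingerprints for a synthetic screen.

    Shifted compounds interpolate from the vehicle profile toward a random
    arrest archetype far enough that the true profile distance (percent
    scale, Euclidean) is at least ``min_shift_pct``; DMSO-like compounds sit
    exactly on the vehicle profile; moderate compounds receive small shifts
    (distance 2-6) that a screen should not call.  Returns the per-compound
    truth plus each compound's true profile distance.
    """
    rng = np.random.default_rng(seed)
    base = dmso_truth.as_array()
    truth: dict[str, PhaseFractions] = {}
    shift: dict[str, float] = {}

    def towards(target: np.ndarray, dist_pct: float) -> PhaseFractions:
        direction = target - base
        norm = 100.0 * float(np.sqrt((direction**2).sum()))
        frac = base + direction * (dist_pct / norm)
        frac = np.clip(frac, 0.0, None)
        frac = frac / frac.sum()
        return PhaseFractions(*frac)

    names = list(ARCHETYPES)
    for i in range(n_shifted):
        target = np.array(ARCHETYPES[names[int(rng.integers(len(names)))]])
        full = 100.0 * float(np.sqrt(((target - base) ** 2).sum()))
        dist = float(rng.uniform(min_shift_pct, max(min_shift_pct, 0.95 * full)))
        comp = f"shifted_{i:03d}"
        truth[comp] = towards(target, dist)
        shift[comp] = 100.0 * float(
            np.sqrt(((truth[comp].as_array() - base) ** 2).sum())
        )
    for i in range(n_dmso_like):
        comp = f"inactive_{i:03d}"
        truth[comp] = dmso_truth
        shift[comp] = 0.0
    for i in range(n_moderate):
        target = np.array(ARCHETYPES[names[int(rng.integers(len(names)))]])
        comp = f"moderate_{i:03d}"
        truth[comp] = towards(target, float(rng.uniform(2.0, 6.0)))
        shift[comp] = 100.0 * float(
            np.sqrt(((truth[comp].as_array() - base) ** 2).sum())
        )
    return truth, shift


def write_events_long(events: dict[str, WellEvents], path) -> None:
    """One long-format delimited file per plate: columns well_id, intensity."""
    frames = [
        pd.DataFrame({"well_id": ev.well_id, "intensity": ev.intensities})
        for _, ev in sorted(events.items())
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_events_long(path) -> dict[str, WellEvents]:
    df = pd.read_csv(path, dtype={"well_id": str})
    return {
        wid: WellEvents(well_id=wid, intensities=grp["intensity"].to_numpy(float))
        for wid, grp in df.groupby("well_id", sort=True)
    }
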