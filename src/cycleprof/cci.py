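"""Cell-cycle fingerprints and the Cell Cycle Index (CCI).

A fingerprint is the four-vector <G1, S, G2/M, subG1> of phase percentages
for one treated well.  The CCI of a drug is the Euclidean norm of its
fingerprint minus the DMSO (vehicle) reference fingerprint,

    CCI = sqrt(RG1^2 + RS^2 + RG2M^2 + RsG1^2),

a single magnitude of cell-cycle perturbation on the percent scale; hit
selection keeps compounds with CCI strictly above a cutoff (default 10).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from cycleprof.errors import ValidationError
from cycleprof.synthcyto import PhaseFractions

#: tolerance on the 100% sum, matching rounding in published tables
SUM_TOL = 0.5


@dataclass(frozen=True)
class Fingerprint:
    """Phase percentages for one compound (or control) well."""

    compound: str
    g1: float
    s: float
    g2m: float
    subg1: float

    def __post_init__(self) -> None:
        for name in ("g1", "s", "g2m", "subg1"):
            v = getattr(self, name)
            if not (0.0 <= v <= 100.0):
                raise ValidationError(f"{self.compound}: {name}={v} outside [0, 100]")

    @property
    def total(self) -> float:
        return self.g1 + self.s + self.g2m + self.subg1

    @property
    def normalized(self) -> bool:
        """True when the four percentages sum to 100 within 0.5."""
        return abs(self.total - 100.0) <= SUM_TOL

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.g1, self.s, self.g2m, self.subg1)

    @classmethod
    def from_fractions(cls, compound: str, frac: PhaseFractions) -> "Fingerprint":
        return cls(compound, 100 * frac.g1, 100 * frac.s, 100 * frac.g2m, 100 * frac.subg1)


@dataclass(frozen=True)
class RelativeFingerprint:
    """Signed differences <RG1, RS, RG2/M, RsG1> from the DMSO reference."""

    compound: str
    rg1: float
    rs: float
    rg2m: float
    rsg1: float

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.rg1, self.rs, self.rg2m, self.rsg1)


def dmso_reference(dmso_fingerprints: list[Fingerprint]) -> Fingerprint:
    """Component-wise mean of the plate's DMSO wells (the reference point)."""
    if not dmso_fingerprints:
        raise ValidationError("need at least one DMSO fingerprint")
    n = len(dmso_fingerprints)
    return Fingerprint(
        compound="DMSO_REF",
        g1=sum(f.g1 for f in dmso_fingerprints) / n,
        s=sum(f.s for f in dmso_fingerprints) / n,
        g2m=sum(f.g2m for f in dmso_fingerprints) / n,
        subg1=sum(f.subg1 for f in dmso_fingerprints) / n,
    )


def relative_fingerprint(drug: Fingerprint, ref: Fingerprint) -> RelativeFingerprint:
    """drug - reference, component-wise, in (G1, S, G2/M, subG1) order."""
    return RelativeFingerprint(
        compound=drug.compound,
        rg1=drug.g1 - ref.g1,
        rs=drug.s - ref.s,
        rg2m=drug.g2m - ref.g2m,
        rsg1=drug.subg1 - ref.subg1,
    )


def cell_cycle_index(r: RelativeFingerprint) -> float:
    """Euclidean norm of the relative fingerprint; 0 iff identical to DMSO."""
    return math.sqrt(r.rg1**2 + r.rs**2 + r.rg2m**2 + r.rsg1**2)


def select_hits(ccis: dict[str, float], cutoff: float = 10.0) -> list[str]:
    """Compounds with CCI strictly greater than the cutoff, strongest first
    (ties broken alphabetically)."""
    if cutoff < 0:
        raise ValidationError(f"cutoff must be >= 0, got {cutoff}")
    hits = [(name, c) for name, c in ccis.items() if c > cutoff]
    hits.sort(key=lambda nc: (-nc[1], nc[0]))
    return [name for name, _ in hits]


def cci_table(
    fingerprints: list[Fingerprint], ref: Fingerprint, cutoff: float = 10.0
) -> pd.DataFrame:
    """Relative fingerprints, CCI and hit flag for a batch of compounds."""
    rows = []
    for fp in fingerprints:
        r = relative_fingerprint(fp, ref)
        cci = cell_cycle_index(r)
        rows.append({"compound": fp.compound, "rg1": r.rg1, "rs": r.rs,
                     "rg2m": r.rg2m, "rsg1": r.rsg1, "cci": cci, "hit": cci > cutoff})
    df = pd.DataFrame(rows, columns=["compound", "rg1", "rs", "rg2m", "rsg1", "cci", "hit"])
    return df.sort_values(["cci", "compound"], ascending=[False, True], ignore_index=True)
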