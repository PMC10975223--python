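"""Unit conversion and clinical banding for ponatinib exposure and molecular response.

Ponatinib efficacy thresholds are defined pharmacologically in molar units
(10 / 20 / 40 nM: minimal anti-proliferative activity, efficacy against
unmutated BCR::ABL1, and suppression of mutant-clone selection including
T315I) and communicated clinically in mass units (5.3 / 10.7 / 21.3 ng/mL at
a free-base molar mass of 532.56 g/mol).  The canonical internal
representation is molar; mass values are always derived, and rounding happens
only at the display layer (round-half-up, 1 decimal place by default).

Molecular response is banded on the BCR::ABL1/ABL1 International Scale (IS%):
DMR (deep molecular response) at IS% <= 0.01, MR3 at <= 0.1, MR2 at <= 1,
below-MR2 otherwise.  Boundaries are inclusive downward, following ELN usage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from enum import IntEnum

from .exceptions import DomainError

#: Free-base molar mass of ponatinib, g/mol.
PONATINIB_MOLAR_MASS_G_PER_MOL = 532.56


def nanomolar_to_ng_per_ml(
    x_nm: float, molar_mass_g_per_mol: float = PONATINIB_MOLAR_MASS_G_PER_MOL
) -> float:
    """Convert a molar concentration (nM) to a mass concentration (ng/mL).

    Exact arithmetic: ``x_nm * molar_mass / 1000``; no hidden rounding.
    """
    if not math.isfinite(x_nm) or x_nm < 0:
        raise DomainError(f"molar concentration must be finite and >= 0, got {x_nm!r}")
    if not math.isfinite(molar_mass_g_per_mol) or molar_mass_g_per_mol <= 0:
        raise DomainError(f"molar mass must be finite and > 0, got {molar_mass_g_per_mol!r}")
    return x_nm * molar_mass_g_per_mol / 1000.0


def ng_per_ml_to_nanomolar(
    x_ng_ml: float, molar_mass_g_per_mol: float = PONATINIB_MOLAR_MASS_G_PER_MOL
) -> float:
    """Inverse of :func:`nanomolar_to_ng_per_ml`."""
    if not math.isfinite(x_ng_ml) or x_ng_ml < 0:
        raise DomainError(f"mass concentration must be finite and >= 0, got {x_ng_ml!r}")
    if not math.isfinite(molar_mass_g_per_mol) or molar_mass_g_per_mol <= 0:
        raise DomainError(f"molar mass must be finite and > 0, got {molar_mass_g_per_mol!r}")
    return x_ng_ml * 1000.0 / molar_mass_g_per_mol


def display_round(x: float, ndigits: int = 1) -> float:
    """Round-half-up for display (so 10.65 ng/mL renders as 10.7, not 10.6)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


class MolecularResponseBand(IntEnum):
    """Ordered molecular-response bands on the International Scale (deeper = larger)."""

    BELOW_MR2 = 0
    MR2 = 1
    MR3 = 2
    DMR = 3


class CminBand(IntEnum):
    """Ordered trough-exposure bands (higher exposure = larger)."""

    BELOW_MINIMAL = 0
    MINIMAL = 1
    UNMUTATED_EFFICACIOUS = 2
    MUTATION_SUPPRESSING = 3


@dataclass(frozen=True)
class ConcentrationThresholds:
    """Efficacy thresholds for ponatinib trough concentration, stored in nM.

    Defaults are 10 / 20 / 40 nM, i.e. 5.33 / 10.65 / 21.30 ng/mL at the
    ponatinib free-base molar mass.  A clinic preferring the literal assay
    LLOQ of 5.0 ng/mL as the minimal cut-off can build thresholds with
    :meth:`from_ng_per_ml`.
    """

    minimal_nm: float = 10.0
    unmutated_nm: float = 20.0
    mutation_suppressing_nm: float = 40.0
    molar_mass_g_per_mol: float = PONATINIB_MOLAR_MASS_G_PER_MOL

    def __post_init__(self):
        vals = (self.minimal_nm, self.unmutated_nm, self.mutation_suppressing_nm)
        if not all(math.isfinite(v) and v > 0 for v in vals):
            raise DomainError(f"thresholds must be finite and > 0, got {vals}")
        if not (self.minimal_nm < self.unmutated_nm < self.mutation_suppressing_nm):
            raise DomainError(f"thresholds must be strictly increasing, got {vals}")
        if not math.isfinite(self.molar_mass_g_per_mol) or self.molar_mass_g_per_mol <= 0:
            raise DomainError("molar mass must be finite and > 0")

    @classmethod
    def from_ng_per_ml(
        cls,
        minimal: float,
        unmutated: float,
        mutation_suppressing: float,
        molar_mass_g_per_mol: float = PONATINIB_MOLAR_MASS_G_PER_MOL,
    ) -> "ConcentrationThresholds":
        """Build thresholds from mass-unit cut-offs (converted to the molar canon)."""
        return cls(
            minimal_nm=ng_per_ml_to_nanomolar(minimal, molar_mass_g_per_mol),
            unmutated_nm=ng_per_ml_to_nanomolar(unmutated, molar_mass_g_per_mol),
            mutation_suppressing_nm=ng_per_ml_to_nanomolar(mutation_suppressing, molar_mass_g_per_mol),
            molar_mass_g_per_mol=molar_mass_g_per_mol,
        )

    def as_ng_per_ml(self) -> tuple[float, float, float]:
        """The three cut-offs converted to ng/mL (full precision, unrounded)."""
        m = self.molar_mass_g_per_mol
        return (
            nanomolar_to_ng_per_ml(self.minimal_nm, m),
            nanomolar_to_ng_per_ml(self.unmutated_nm, m),
            nanomolar_to_ng_per_ml(self.mutation_suppressing_nm, m),
        )


#: Package-wide default thresholds (10/20/40 nM).
DEFAULT_THRESHOLDS = ConcentrationThresholds()


def classify_molecular_response(is_percent: float) -> MolecularResponseBand:
    """Band a BCR::ABL1/ABL1 IS% ratio; boundaries inclusive downward (<=)."""
    if not math.isfinite(is_percent) or is_percent < 0:
        raise DomainError(f"IS% must be finite and >= 0, got {is_percent!r}")
    if is_percent <= 0.01:
        return MolecularResponseBand.DMR
    if is_percent <= 0.1:
        return MolecularResponseBand.MR3
    if is_percent <= 1.0:
        return MolecularResponseBand.MR2
    return MolecularResponseBand.BELOW_MR2


def classify_cmin(
    c_ng_ml: float, thresholds: ConcentrationThresholds = DEFAULT_THRESHOLDS
) -> CminBand:
    """Band a trough concentration; attainment is inclusive (``>=`` the cut-off)."""
    if not math.isfinite(c_ng_ml) or c_ng_ml < 0:
        raise DomainError(f"concentration must be finite and >= 0, got {c_ng_ml!r}")
    minimal, unmutated, suppressing = thresholds.as_ng_per_ml()
    if c_ng_ml >= suppressing:
        return CminBand.MUTATION_SUPPRESSING
    if c_ng_ml >= unmutated:
        return CminBand.UNMUTATED_EFFICACIOUS
    if c_ng_ml >= minimal:
        return CminBand.MINIMAL
    return CminBand.BELOW_MINIMAL
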