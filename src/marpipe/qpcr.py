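"""qPCR efficiency estimation, Ct calling and relative quantification.

Relative quantities follow the efficiency-corrected ratio

    ratio = E_B ** Ct_B / E_A ** Ct_A

with gene A the target (e.g. a GFP transgene) and gene B the endogenous
reference (GAPDH for genomic DNA copy number, eEF1A for mRNA).  The ratio
estimates the target:reference template ratio; expressing each sample's
ratio relative to a control condition (set to 1) gives fold changes, and
dividing an mRNA fold by a copy-number fold gives per-copy expression.

Efficiencies are estimated per curve from the log-linear phase
(window-of-linearity approach): after baseline subtraction, the 4–6 cycle
window maximising the R² of log10(fluorescence) against cycle is selected
and E = 10^slope.  The baseline is the mean of the first five cycles when
those cycles form a plateau (relative spread < 0.5), and zero otherwise —
baseline subtraction is only meaningful when an early plateau exists.
Candidate windows are confined to the exponential region: corrected
fluorescence at most 2% of the plateau amplitude (above that the saturating
chemistry visibly depresses the slope) and at least 20× the early-cycle
noise; if no window qualifies the restriction is dropped before giving up.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import (
    ConfigurationError,
    DegenerateInputError,
    EfficiencyOutOfRangeError,
    NoAmplificationError,
    NoCtError,
    ParseError,
    ValidationError,
)

_E_LOW, _E_HIGH = 1.0, 2.2  # plausible per-cycle amplification factors


@dataclass
class AmplificationCurve:
    """One well's raw qPCR fluorescence readings."""

    cycles: np.ndarray
    fluorescence: np.ndarray
    well: str = ""
    gene: str = ""

    def __post_init__(self):
        self.cycles = np.asarray(self.cycles, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if len(self.cycles) != len(self.fluorescence):
            raise ValidationError("cycles and fluorescence must have equal length")
        if len(self.cycles) < 15:
            raise ValidationError("need at least 15 cycles")
        if np.any(np.diff(self.cycles) <= 0):
            raise ValidationError("cycles must be strictly increasing")
        if not np.all(np.isfinite(self.fluorescence)):
            raise ValidationError("fluorescence must be finite")


@dataclass
class RelativeQuantResult:
    """Efficiencies, Cts and the resulting relative quantity for one condition."""

    condition: str
    e_target: float
    ct_target: float
    e_reference: float
    ct_reference: float
    ratio: float
    fold_vs_control: float | None = None


# ---------------------------------------------------------------------------
# Efficiency and Ct
# ---------------------------------------------------------------------------

def _best_loglinear_window(corrected: np.ndarray, cycles: np.ndarray, upper: float, lower: float):
    """Best (r2, width, start, slope) over 4–6 cycle windows within bounds.

    Eligible cycles satisfy ``lower < corrected <= upper``.  Returns None
    when no window qualifies.  Windows with non-positive slope or zero
    log-variance are not amplification and are skipped.
    """
    n = len(corrected)
    best = None
    for width in (6, 5, 4):
        for start in range(0, n - width + 1):
            seg = corrected[start : start + width]
            if np.any(seg <= lower) or np.any(seg > upper) or np.any(seg <= 0):
                continue
            x = cycles[start : start + width]
            y = np.log10(seg)
            ss_tot = np.sum((y - y.mean()) ** 2)
            if ss_tot == 0:
                continue
            slope, intercept = np.polyfit(x, y, 1)
            if slope <= 0:
                continue
            resid = y - (slope * x + intercept)
            r2 = 1.0 - np.sum(resid**2) / ss_tot
            key = (r2, width, -start)
            if best is None or key > best[0]:
                best = (key, slope)
    return best


def estimate_efficiency(curve: AmplificationCurve, return_window: bool = False):
    """Estimate the per-cycle amplification efficiency E from one curve.

    See the module docstring for the window-of-linearity procedure.  Raises
    :class:`NoAmplificationError` when no 4-cycle window of positive
    baseline-corrected fluorescence with rising log-linear signal exists,
    and :class:`EfficiencyOutOfRangeError` when E falls outside (1, 2.2].
    """
    f = curve.fluorescence
    early = f[:5]
    mean_early = float(np.mean(early))
    spread = np.ptp(early) / abs(mean_early) if mean_early != 0 else np.inf
    if spread < 0.5:  # an early plateau exists: subtract it
        baseline = mean_early
        noise_floor = 20.0 * float(np.std(early, ddof=1))
    else:
        baseline, noise_floor = 0.0, 0.0
    corrected = f - baseline
    upper = 0.02 * float(np.max(corrected))  # stay out of the saturating phase
    best = _best_loglinear_window(corrected, curve.cycles, upper, noise_floor)
    if best is None:
        best = _best_loglinear_window(corrected, curve.cycles, np.inf, noise_floor)
    if best is None:
        raise NoAmplificationError(
            f"curve {curve.well!r} has no usable exponential phase"
        )
    (r2, width, neg_start), slope = best
    e = 10.0**slope
    if not (_E_LOW < e <= _E_HIGH):
        raise EfficiencyOutOfRangeError(
            f"curve {curve.well!r}: estimated E = {e:.3f} outside ({_E_LOW}, {_E_HIGH}]"
        )
    if return_window:
        return float(e), (-neg_start, -neg_start + width, float(r2))
    return float(e)


def call_ct(curve: AmplificationCurve, threshold: float) -> float:
    """Interpolated cycle at which the curve first crosses ``threshold``.

    Interpolation is linear on the log10(fluorescence) scale between the
    bracketing cycles; only the first crossing counts.  The threshold must
    sit above the early-cycle noise of the raw curve.
    """
    if threshold <= 0:
        raise ConfigurationError("Ct threshold must be positive")
    f = curve.fluorescence
    above = f >= threshold
    if not above.any():
        raise NoCtError(f"curve {curve.well!r} never reaches threshold {threshold}")
    i = int(np.argmax(above))
    if i == 0:
        return float(curve.cycles[0])
    f0, f1 = f[i - 1], f[i]
    c0, c1 = curve.cycles[i - 1], curve.cycles[i]
    if f0 <= 0:
        return float(c1)
    frac = (np.log10(threshold) - np.log10(f0)) / (np.log10(f1) - np.log10(f0))
    return float(c0 + frac * (c1 - c0))


# ---------------------------------------------------------------------------
# Ratios and folds
# ---------------------------------------------------------------------------

def _check_efficiency(e: float, who: str) -> None:
    if not (_E_LOW < e <= _E_HIGH):
        raise ValidationError(f"{who} efficiency {e} outside ({_E_LOW}, {_E_HIGH}]")


def relative_quantity(e_a: float, ct_a: float, e_b: float, ct_b: float) -> float:
    """E_B ** Ct_B / E_A ** Ct_A — target quantity relative to the reference."""
    _check_efficiency(e_a, "target")
    _check_efficiency(e_b, "reference")
    if ct_a <= 0 or ct_b <= 0:
        raise ValidationError("Ct values must be positive")
    return e_b**ct_b / e_a**ct_a


def fold_vs_control(sample_ratios, control_ratio: float):
    """Each sample ratio divided by the control ratio (control maps to 1)."""
    control = float(control_ratio)
    if control <= 0:
        raise DegenerateInputError("control ratio must be positive")
    return [float(r) / control for r in np.atleast_1d(np.asarray(sample_ratios, float))]


def expression_per_copy(mrna_fold: float, copy_fold: float) -> float:
    """mRNA fold change normalised to the transgene copy-number fold change."""
    if copy_fold <= 0:
        raise ValidationError("copy-number fold must be positive")
    return mrna_fold / copy_fold


# ---------------------------------------------------------------------------
# Plate-level workflow
# ---------------------------------------------------------------------------

def _read_table(path) -> pd.DataFrame:
    """Read a TSV or CSV table (sniffing the separator trips on one-column files)."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] == 1 and "," in str(df.columns[0]):
        df = pd.read_csv(path)
    return df


def read_curves(path) -> dict[str, AmplificationCurve]:
    """Read a wide curve table: first column cycle, one column per well."""
    df = _read_table(path)
    if df.shape[1] < 2:
        raise ParseError("curve table needs a cycle column plus wells", path)
    cycles = df.iloc[:, 0].to_numpy(dtype=float)
    return {
        str(col): AmplificationCurve(cycles, df[col].to_numpy(dtype=float), well=str(col))
        for col in df.columns[1:]
    }


def read_sample_sheet(path) -> pd.DataFrame:
    """Read a well → (gene, condition, replicate) sample sheet."""
    df = _read_table(path)
    required = {"well", "gene", "condition"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"sample sheet missing columns {sorted(missing)}", path)
    df["well"] = df["well"].astype(str)
    return df


def quantify_plate(
    curves: dict[str, AmplificationCurve],
    sheet: pd.DataFrame,
    target: str,
    reference: str,
    threshold: float,
    control_condition: str | None = None,
) -> list[RelativeQuantResult]:
    """Per-condition relative quantities from a plate of curves.

    Efficiencies are estimated per well and averaged per gene (efficiency is
    an amplicon property); replicate Cts are averaged per condition before
    the ratio is computed.  When a control condition is named, fold changes
    relative to it (control = 1) are attached.
    """
    unmatched = [w for w in sheet["well"] if w not in curves]
    if unmatched:
        raise ValidationError(f"sample sheet references missing wells: {unmatched}")
    sheet = sheet[sheet["gene"].isin([target, reference])]
    if sheet.empty:
        raise ValidationError(f"no wells for genes {target!r}/{reference!r}")

    eff: dict[str, float] = {}
    for gene in (target, reference):
        wells = sheet.loc[sheet["gene"] == gene, "well"]
        if wells.empty:
            raise ValidationError(f"no wells for gene {gene!r}")
        eff[gene] = float(np.mean([estimate_efficiency(curves[w]) for w in wells]))

    results: list[RelativeQuantResult] = []
    for condition, grp in sheet.groupby("condition", sort=False):
        cts: dict[str, float] = {}
        for gene in (target, reference):
            wells = grp.loc[grp["gene"] == gene, "well"]
            if wells.empty:
                raise ValidationError(
                    f"condition {condition!r} has no wells for gene {gene!r}"
                )
            cts[gene] = float(np.mean([call_ct(curves[w], threshold) for w in wells]))
        ratio = relative_quantity(eff[target], cts[target], eff[reference], cts[reference])
        results.append(
            RelativeQuantResult(
                condition=str(condition),
                e_target=eff[target],
                ct_target=cts[target],
                e_reference=eff[reference],
                ct_reference=cts[reference],
                ratio=ratio,
            )
        )

    if control_condition is not None:
        control = next(
            (r for r in results if r.condition == control_condition), None
        )
        if control is None:
            raise ValidationError(f"control condition {control_condition!r} not found")
        folds = fold_vs_control([r.ratio for r in results], control.ratio)
        for r, f in zip(results, folds):
            r.fold_vs_control = f
    return results


def results_table(results: list[RelativeQuantResult]) -> pd.DataFrame:
    """Results as a tidy per-condition DataFrame."""
    return pd.DataFrame(
        {
            "condition": [r.condition for r in results],
            "E_target": [r.e_target for r in results],
            "Ct_target": [r.ct_target for r in results],
            "E_reference": [r.e_reference for r in results],
            "Ct_reference": [r.ct_reference for r in results],
            "ratio": [r.ratio for r in results],
            "fold_vs_control": [r.fold_vs_control for r in results],
        }
    )
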