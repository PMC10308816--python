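"""Normalization and group analysis of concentration-series SHAPE reads.

Capillary-electrophoresis read tables collected at several reagent
concentrations are made comparable across channels by clipping negative
reads to zero, dividing by the channel total, and multiplying by the
channel's nominal concentration.  This enforces a linear dependence of the
average read on concentration while preserving the position- and
concentration-dependence of the signal.  Per-nucleotide power laws
``R = alpha * C^beta`` are then fitted across channels, and exponents are
compared between structural groups (nucleotides inside GNRA tetraloops vs
all others) with a two-sample t-test.  Because ``alpha`` extrapolates to
1 M and is highly sensitive to errors on ``beta``, the more robust shifted
amplitude ``alpha * 0.0125^beta`` (the reactivity shifted to 12.5 mM, the
highest channel) is reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from gcprobe.gc_core import GCProbeError

#: Concentration (mol/L) to which fitted amplitudes are shifted.
SHIFT_CONCENTRATION_M = 0.0125


def normalize_reads(
    reads: pd.DataFrame, channels: Mapping[str, float]
) -> pd.DataFrame:
    """Normalize raw reads channel by channel.

    Per channel: negative reads are clipped to zero first (dividing by a
    total that still contains negatives could flip signs), the clipped
    reads are divided by the channel sum, and the result is scaled by the
    channel's nominal concentration expressed in mM.

    Parameters
    ----------
    reads:
        Table with one column per concentration channel (other columns are
        passed through untouched).
    channels:
        Maps channel column name to its nominal concentration in mol/L.

    Raises
    ------
    GCProbeError
        If a channel sums to zero after clipping.
    """
    if len(channels) == 0:
        raise GCProbeError("no concentration channels supplied")
    out = reads.copy()
    for col, conc in channels.items():
        if col not in reads.columns:
            raise GCProbeError(f"channel column {col!r} missing from reads table")
        clipped = reads[col].to_numpy(dtype=float).clip(min=0.0)
        total = clipped.sum()
        if total <= 0:
            raise GCProbeError(f"channel {col!r} sums to zero after clipping")
        out[col] = clipped / total * (conc * 1e3)
    return out


def fit_concentration_series(
    normalized: pd.DataFrame, channels: Mapping[str, float]
) -> pd.DataFrame:
    """Per-row power-law fit of normalized reads against concentration.

    Ordinary least squares of log(read) on log(C), with C in mol/L.  Rows
    with any nonpositive normalized value across the channels are flagged
    ``fit_ok = False`` with NaN coefficients rather than silently dropped.

    Returns the input table (channel columns excluded) extended with
    ``alpha``, ``beta``, ``se_alpha``, ``se_beta``, ``shifted_amplitude``
    (= alpha * 0.0125^beta) and ``fit_ok``.
    """
    cols = list(channels)
    if len(cols) < 2:
        raise GCProbeError("need at least two concentration channels to fit")
    conc = np.array([channels[c] for c in cols], dtype=float)
    order = np.argsort(conc)
    conc = conc[order]
    cols = [cols[i] for i in order]
    logC = np.log(conc)
    meta = normalized.drop(columns=cols)
    records = []
    for _, row in normalized.iterrows():
        y = row[cols].to_numpy(dtype=float)
        if np.any(y <= 0):
            records.append(
                dict(alpha=np.nan, beta=np.nan, se_alpha=np.nan, se_beta=np.nan,
                     shifted_amplitude=np.nan, fit_ok=False)
            )
            continue
        res = stats.linregress(logC, np.log(y))
        alpha = float(np.exp(res.intercept))
        beta = float(res.slope)
        se_beta = float(res.stderr) if np.isfinite(res.stderr) else 0.0
        se_alpha = alpha * (
            float(res.intercept_stderr) if np.isfinite(res.intercept_stderr) else 0.0
        )
        records.append(
            dict(
                alpha=alpha,
                beta=beta,
                se_alpha=se_alpha,
                se_beta=se_beta,
                shifted_amplitude=alpha * SHIFT_CONCENTRATION_M**beta,
                fit_ok=True,
            )
        )
    return pd.concat([meta.reset_index(drop=True), pd.DataFrame.from_records(records)], axis=1)


@dataclass(frozen=True)
class GroupComparison:
    """Two-group comparison of fitted exponents and shifted amplitudes."""

    mean_beta_gnra: float
    mean_beta_other: float
    mean_amp_gnra: float
    mean_amp_other: float
    t_beta: float | None
    p_beta: float | None
    t_amp: float | None
    p_amp: float | None
    mean_beta_first_g: float | None = None
    mean_amp_first_g: float | None = None


def compare_groups(
    fits: pd.DataFrame,
    gnra_col: str = "gnra",
    first_g_col: str | None = "first_g",
    welch: bool = True,
) -> GroupComparison:
    """Compare beta and shifted amplitude between GNRA and other nucleotides.

    Uses Welch's t-test by default (unequal group sizes and variances are
    the norm here); set ``welch=False`` for the pooled-variance variant.
    Rows with ``fit_ok == False`` are excluded.  G nucleotides in the first
    tetraloop position, where cooperativity is strongest, are additionally
    summarized on their own when flagged.  If either group has fewer than
    two members the test is refused (statistics set to None) while the
    means are still reported.
    """
    ok = fits[fits.get("fit_ok", True) == True]  # noqa: E712
    gnra = ok[ok[gnra_col].astype(bool)]
    other = ok[~ok[gnra_col].astype(bool)]
    if len(gnra) == 0 or len(other) == 0:
        raise GCProbeError("both groups must be non-empty")

    def _test(col: str) -> tuple[float | None, float | None]:
        if len(gnra) < 2 or len(other) < 2:
            return None, None
        t, p = stats.ttest_ind(
            gnra[col], other[col], equal_var=not welch
        )
        return float(t), float(p)

    t_beta, p_beta = _test("beta")
    t_amp, p_amp = _test("shifted_amplitude")
    first_beta = first_amp = None
    if first_g_col is not None and first_g_col in ok.columns:
        fg = ok[ok[first_g_col].astype(bool)]
        if len(fg):
            first_beta = float(fg["beta"].mean())
            first_amp = float(fg["shifted_amplitude"].mean())
    return GroupComparison(
        mean_beta_gnra=float(gnra["beta"].mean()),
        mean_beta_other=float(other["beta"].mean()),
        mean_amp_gnra=float(gnra["shifted_amplitude"].mean()),
        mean_amp_other=float(other["shifted_amplitude"].mean()),
        t_beta=t_beta,
        p_beta=p_beta,
        t_amp=t_amp,
        p_amp=p_amp,
        mean_beta_first_g=first_beta,
        mean_amp_first_g=first_amp,
    )
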