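"""Per-region transcription-rate estimation and active-region calling.

The model: plasmid (DNA) copies per barcode are Gamma-distributed; RNA counts
given the plasmid copies are Poisson with mean ``alpha * plasmid``, so the
marginal RNA likelihood is negative binomial. ``estimate_alpha`` fits alpha
per region in two stages — a method-of-moments Gamma fit of the DNA counts,
then a 1-D negative-binomial maximum-likelihood fit of the RNA counts with
the barcode's plasmid count as offset. ``call_active`` converts alpha to a
robust standard score against negative controls (median / scaled MAD),
applies a one-sided normal survival test and Benjamini-Hochberg correction,
and calls regions active at the chosen FDR.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

logger = logging.getLogger(__name__)

__all__ = ["estimate_alpha", "call_active", "threshold_active", "nb_loglik"]

MAD_SCALE = 1.4826  # makes MAD consistent with the normal sd


def nb_loglik(alpha: float, rna: np.ndarray, plasmid: np.ndarray, dispersion: float) -> float:
    """Negative-binomial log-likelihood of RNA counts with mean alpha*plasmid.

    ``dispersion`` is the NB2 parameter phi with Var = mu + phi * mu^2;
    phi = 0 reduces to Poisson.
    """
    mu = alpha * plasmid
    if np.any(mu <= 0):
        return -np.inf
    if dispersion <= 0:
        return float(np.sum(rna * np.log(mu) - mu - special.gammaln(rna + 1)))
    r = 1.0 / dispersion
    return float(
        np.sum(
            special.gammaln(rna + r)
            - special.gammaln(r)
            - special.gammaln(rna + 1)
            + r * np.log(r / (r + mu))
            + rna * np.log(mu / (r + mu))
        )
    )


def _moment_dispersion(df: pd.DataFrame) -> float:
    """Pooled NB2 dispersion across regions by the method of moments.

    Uses the per-region ratio estimate of alpha to form fitted means, then
    solves sum((R - mu)^2 - mu) = phi * sum(mu^2) over all barcodes.
    """
    num = 0.0
    den = 0.0
    for _, grp in df.groupby("region_id", sort=False):
        d = grp["dna"].to_numpy(float)
        r = grp["rna"].to_numpy(float)
        ok = d > 0
        if ok.sum() < 2 or r[ok].sum() == 0:
            continue
        a = r[ok].sum() / d[ok].sum()
        mu = a * d[ok]
        num += float(np.sum((r[ok] - mu) ** 2 - mu))
        den += float(np.sum(mu**2))
    if den <= 0:
        return 0.0
    return max(0.0, num / den)


def estimate_alpha(
    counts: pd.DataFrame, dispersion: float | None = None
) -> pd.DataFrame:
    """Estimate the per-region transcription rate alpha.

    Parameters
    ----------
    counts : DataFrame
        Barcode-level table with columns ``region_id, dna, rna`` (and
        optionally ``is_control``).
    dispersion : float, optional
        NB2 dispersion (Var = mu + phi mu^2). When omitted, a single pooled
        moment estimate across regions is used; per-region estimates are too
        unstable at typical barcode counts.

    Returns
    -------
    DataFrame indexed by region with columns ``alpha, log2_alpha, se,
    n_barcodes, n_dropped, dna_gamma_shape, dna_gamma_scale, is_control,
    diagnostic``. Regions with no usable barcode are retained with NaN alpha
    and a diagnostic message, never dropped.
    """
    if dispersion is not None and dispersion < 0:
        raise ValueError(f"dispersion must be >= 0, got {dispersion}")
    required = {"region_id", "dna", "rna"}
    missing = required - set(counts.columns)
    if missing:
        raise ValueError(f"count table is missing columns: {sorted(missing)}")

    phi = _moment_dispersion(counts) if dispersion is None else float(dispersion)

    rows = []
    for region_id, grp in counts.groupby("region_id", sort=False):
        d = grp["dna"].to_numpy(float)
        r = grp["rna"].to_numpy(float)
        is_control = bool(grp["is_control"].iloc[0]) if "is_control" in grp else False
        ok = d > 0
        n_dropped = int((~ok).sum())
        row = {
            "region_id": region_id,
            "alpha": np.nan,
            "log2_alpha": np.nan,
            "se": np.nan,
            "n_barcodes": int(ok.sum()),
            "n_dropped": n_dropped,
            "dna_gamma_shape": np.nan,
            "dna_gamma_scale": np.nan,
            "is_control": is_control,
            "diagnostic": "",
        }
        if ok.sum() == 0:
            row["diagnostic"] = "all DNA counts are zero; alpha undefined"
            rows.append(row)
            continue
        d_ok, r_ok = d[ok], r[ok]
        if n_dropped:
            logger.info("region %s: excluded %d barcodes with dna=0", region_id, n_dropped)

        # stage 1: Gamma method-of-moments fit of the DNA counts
        m, v = d_ok.mean(), d_ok.var(ddof=1) if len(d_ok) > 1 else 0.0
        if v > 0:
            row["dna_gamma_scale"] = v / m
            row["dna_gamma_shape"] = m**2 / v
        plasmid = d_ok  # observed copies stand for the latent plasmid count

        # stage 2: 1-D NB maximum likelihood in alpha with plasmid offset
        a0 = r_ok.sum() / d_ok.sum()
        if a0 <= 0:
            row.update(alpha=0.0, log2_alpha=-np.inf)
            row["diagnostic"] = "all RNA counts are zero"
            rows.append(row)
            continue
        if phi <= 0:
            a_hat = a0  # Poisson MLE with offset is the count ratio
        else:
            res = optimize.minimize_scalar(
                lambda a: -nb_loglik(a, r_ok, plasmid, phi),
                bounds=(a0 * 1e-3, a0 * 1e3),
                method="bounded",
                options={"xatol": a0 * 1e-9},
            )
            a_hat = float(res.x)
        # observed information via central second difference on the log-lik
        h = max(a_hat * 1e-4, 1e-10)
        ll = nb_loglik
        d2 = (
            ll(a_hat + h, r_ok, plasmid, phi)
            - 2 * ll(a_hat, r_ok, plasmid, phi)
            + ll(a_hat - h, r_ok, plasmid, phi)
        ) / h**2
        se = float(np.sqrt(-1.0 / d2)) if d2 < 0 else np.nan
        row.update(alpha=a_hat, log2_alpha=np.log2(a_hat), se=se)
        rows.append(row)

    out = pd.DataFrame(rows).set_index("region_id")
    out.attrs["dispersion"] = phi
    return out


def call_active(
    activity: pd.DataFrame,
    control_ids: set[str] | None = None,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Call active regions from fitted alpha values.

    The robust standard score is ``(alpha - median_ref) / (MAD_ref * 1.4826)``
    where the reference set is the controls when given (or flagged in the
    table) and otherwise all regions. One-sided upper-tail normal p-values
    are Benjamini-Hochberg adjusted over all regions with finite alpha;
    ``active`` means ``q < fdr_threshold``.
    """
    act = activity.copy()
    alpha = act["alpha"].to_numpy(float)

    if control_ids is not None:
        ref_mask = act.index.isin(control_ids)
        ref_name = "control set"
        n_finite_controls = int(np.isfinite(alpha[ref_mask]).sum())
        if n_finite_controls < 5:
            raise ValueError(
                f"need >= 5 controls with finite alpha, got {n_finite_controls}"
            )
    elif "is_control" in act.columns and act["is_control"].any():
        ref_mask = act["is_control"].to_numpy(bool)
        ref_name = "control set"
    else:
        ref_mask = np.ones(len(act), dtype=bool)
        ref_name = "all regions"

    ref = alpha[ref_mask & np.isfinite(alpha)]
    med = float(np.median(ref))
    mad = float(np.median(np.abs(ref - med)))
    if mad == 0:
        raise ValueError(f"MAD of the reference set ({ref_name}) is zero")

    z = (alpha - med) / (mad * MAD_SCALE)
    p = stats.norm.sf(z)
    finite = np.isfinite(p)
    q = np.full_like(p, np.nan)
    if finite.any():
        q[finite] = bh_adjust(p[finite])
    act["z"] = z
    act["p"] = p
    act["q"] = q
    act["active"] = (q < fdr_threshold) & finite
    return act


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p, dtype=float)
    if len(p) == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def threshold_active(activity: pd.DataFrame, log2_cutoff: float = 1.5) -> pd.Series:
    """Binary activity labels by a log2-alpha cutoff (boundary is inactive)."""
    log2a = activity["log2_alpha"]
    return (log2a > log2_cutoff).astype(int).rename("active")
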