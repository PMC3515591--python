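"""TPM normalization and Poisson-model differential expression.

Counts are normalized as transcripts per million (count / library clean
reads x 1e6). Significance of a count pair (x, y) from libraries of
depths N1, N2 uses the Audic-Claverie conditional measure

    q(y|x) = (N2/N1)^y (x+y)! / ( x! y! (1+N2/N1)^(x+y) )

whose two tails are accumulated and doubled (capped at 1). This
symmetric form satisfies q(y|x; N1,N2) = q(x|y; N2,N1), so swapping the
libraries swaps nothing. With t = N2/N1, q(k|x) = (1+t) * NB(k; x+1,
1/(1+t)), so tails come from the negative binomial CDF/SF in log space
(scipy), never from explicit factorials.

A miRNA is called drought-responsive when p < 0.01 and |log2 FC| > 1;
the p-value is the raw test by default, with optional
Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


def tpm(count, total) -> np.ndarray | float:
    """Transcripts per million: count / total * 1e6."""
    total = np.asarray(total, dtype=float)
    if np.any(total <= 0):
        raise ValueError("library total must be positive")
    return np.asarray(count, dtype=float) / total * 1e6


def log2fc(tpm_treatment, tpm_control, floor: float = 0.01):
    """log2(treatment/control) with a small TPM floor so zero counts give
    a finite, direction-preserving ratio."""
    if floor <= 0:
        raise ValueError("floor must be positive")
    t = np.maximum(np.asarray(tpm_treatment, dtype=float), floor)
    c = np.maximum(np.asarray(tpm_control, dtype=float), floor)
    return np.log2(t / c)


def ac_pvalue(x, y, n1, n2):
    """Two-sided Audic-Claverie p-value(s); vectorized over x, y."""
    x = np.atleast_1d(np.asarray(x))
    y = np.atleast_1d(np.asarray(y))
    if np.any(x < 0) or np.any(y < 0):
        raise ValueError("counts must be non-negative")
    if not np.all(np.equal(np.mod(x, 1), 0)) or not np.all(np.equal(np.mod(y, 1), 0)):
        raise ValueError("counts must be integers")
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library totals must be positive")
    x = x.astype(np.int64)
    y = y.astype(np.int64)
    t = n2 / n1
    p_nb = 1.0 / (1.0 + t)
    lower = (1.0 + t) * stats.nbinom.cdf(y, x + 1, p_nb)
    upper = (1.0 + t) * stats.nbinom.sf(y - 1, x + 1, p_nb)
    p = np.minimum(1.0, 2.0 * np.minimum(lower, upper))
    return p if p.size > 1 else float(p[0])


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def expression_table(counts: pd.DataFrame, totals: dict, control: str,
                     treatment: str, floor: float = 0.01,
                     adjust: bool = False) -> pd.DataFrame:
    """Per-miRNA expression records for one contrast.

    counts: DataFrame with one count column per library (index = miRNA
    id); totals: library -> clean-read total. Returns a table with raw
    counts, TPMs, log2 fold change (treatment over control), p-value
    and the significance call.
    """
    x = counts[control].to_numpy(np.int64)
    y = counts[treatment].to_numpy(np.int64)
    n1, n2 = float(totals[control]), float(totals[treatment])
    tc, tt = tpm(x, n1), tpm(y, n2)
    lfc = log2fc(tt, tc, floor=floor)
    p = np.atleast_1d(ac_pvalue(x, y, n1, n2))
    if adjust:
        p = bh_adjust(p)
    df = pd.DataFrame({
        "mirna_id": counts.index,
        "count_control": x, "count_treatment": y,
        "tpm_control": tc, "tpm_treatment": tt,
        "log2fc": lfc, "p_value": p,
    })
    return call_de(df)


def call_de(records: pd.DataFrame, p_cut: float = 0.01,
            lfc_cut: float = 1.0) -> pd.DataFrame:
    """Flag significant records (p < p_cut and |log2fc| > lfc_cut) and
    attach a direction column ('up'/'down'/'')."""
    rec = records.copy()
    sig = (rec.p_value < p_cut) & (rec.log2fc.abs() > lfc_cut)
    rec["significant"] = sig
    rec["direction"] = np.where(~sig, "", np.where(rec.log2fc > 0, "up", "down"))
    return rec


def de_summary(records: pd.DataFrame) -> dict:
    sig = records[records.significant]
    return {"n": int(len(records)), "significant": int(len(sig)),
            "up": int((sig.direction == "up").sum()),
            "down": int((sig.direction == "down").sum())}
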