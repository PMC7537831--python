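"""Gene categorization from a TPM matrix.

Average log2 expression across contexts is bimodal: a low-expression
subpopulation (LES, genes off almost everywhere) superposed with a
high-expression subpopulation (HES).  A two-component Gaussian fit to the
per-gene means yields the four category thresholds

* high:  log2(TPM) > mu_HES
* rare:  log2(TPM) < mu_LES
* low:   log2(TPM) < mu_LES + sigma_LES (and not rare)
* moderate: everything between,

followed by a relative-expression heuristic that promotes or demotes
*moderate* entries using fold-change jumps along the sorted cross-context
profile of each gene.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

from .core import CATEGORIES, ConfigurationError, MergeError

__all__ = [
    "PSEUDOCOUNT",
    "GaussianFit",
    "CategorizationThresholds",
    "log2_tpm",
    "fit_bimodal",
    "categorize_absolute",
    "recategorize_relative",
    "recategorize_table",
    "categorize",
    "read_tpm",
    "write_categories",
    "read_categories",
]

#: added to TPM before log2 so zero expression stays finite (-3.32 log2 units)
PSEUDOCOUNT = 0.1


@dataclass
class GaussianFit:
    """Two-component Gaussian mixture on log2(TPM + 0.1); units are log2-TPM."""

    mu_hes: float
    sigma_hes: float
    mu_les: float
    sigma_les: float
    weight_hes: float
    weight_les: float
    degenerate: bool = False

    def __post_init__(self):
        if self.mu_les > self.mu_hes:
            raise MergeError("component ordering violated: mu_LES > mu_HES")


@dataclass
class CategorizationThresholds:
    """Hard category cutoffs (log2-TPM): rare < low < high, plus the
    relative-expression gate tau_rel = mu_HES - sigma_HES."""

    high: float
    low: float
    rare: float
    tau_rel: float

    def __post_init__(self):
        if not (self.rare < self.low < self.high):
            raise MergeError(
                f"threshold ordering violated: rare={self.rare} low={self.low} high={self.high}"
            )

    @classmethod
    def from_fit(cls, fit: GaussianFit) -> "CategorizationThresholds":
        high = fit.mu_hes
        low = fit.mu_les + fit.sigma_les
        rare = fit.mu_les
        if high <= low:
            # collapsed fit: keep the forced ordering, flag upstream via
            # fit.degenerate (set by fit_bimodal)
            high = low + 1e-6
        return cls(high=high, low=low, rare=rare, tau_rel=fit.mu_hes - fit.sigma_hes)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "CategorizationThresholds":
        return cls(**json.loads(Path(path).read_text()))


def log2_tpm(tpm, pseudocount: float = PSEUDOCOUNT):
    return np.log2(np.asarray(tpm, dtype=float) + pseudocount)


def fit_bimodal(log2_values, seed: int = 0) -> GaussianFit:
    """Maximum-likelihood two-component Gaussian fit to log2 expression.

    The component with the larger mean is labelled HES.  A fit is flagged
    degenerate when one component carries <1% of the mass or the component
    separation (mu_HES - mu_LES) / (2 sqrt(sigma_HES sigma_LES)) falls
    below 1 — the standard condition for the mixture to be bimodal at
    all; components are still returned ordered by mean.
    """
    x = np.asarray(log2_values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 100:
        raise ConfigurationError(f"need >= 100 finite values to fit, got {x.size}")
    gm = GaussianMixture(n_components=2, n_init=3, random_state=seed, reg_covar=1e-6)
    gm.fit(x.reshape(-1, 1))
    means = gm.means_.ravel()
    sigmas = np.sqrt(gm.covariances_.ravel())
    weights = gm.weights_.ravel()
    hi, lo = (0, 1) if means[0] >= means[1] else (1, 0)
    separation = (means[hi] - means[lo]) / (2.0 * np.sqrt(sigmas[hi] * sigmas[lo]))
    degenerate = bool(weights[hi] < 0.01 or weights[lo] < 0.01 or separation < 1.0)
    return GaussianFit(
        mu_hes=float(means[hi]),
        sigma_hes=float(sigmas[hi]),
        mu_les=float(means[lo]),
        sigma_les=float(sigmas[lo]),
        weight_hes=float(weights[hi]),
        weight_les=float(weights[lo]),
        degenerate=degenerate,
    )


def categorize_absolute(
    tpm: pd.DataFrame, thresholds: CategorizationThresholds
) -> pd.DataFrame:
    """Per-cell absolute categorization of a gene x context TPM matrix.

    Inequalities are strict for high and rare, so a value exactly at a
    threshold resolves to the lower category.
    """
    values = tpm.to_numpy(dtype=float)
    if (values < 0).any():
        raise ConfigurationError("negative TPM values in expression matrix")
    x = log2_tpm(values)
    cats = np.full(x.shape, "moderate", dtype=object)
    cats[x < thresholds.low] = "low"
    cats[x < thresholds.rare] = "rare"
    cats[x > thresholds.high] = "high"
    return pd.DataFrame(cats, index=tpm.index, columns=tpm.columns)


def recategorize_relative(
    tpm_profile: pd.Series,
    categories: pd.Series,
    thresholds: CategorizationThresholds,
    fc_edge: float = 4.0,
    fc_inner: float = 1.5,
) -> pd.Series:
    """Relative-expression pass for one gene across its contexts.

    Contexts are sorted ascending by TPM; each of the n-1 intervals is
    tested for a fold-change jump (computed on TPM + 0.1).  A jump above
    ``fc_edge`` in the first interval or ``fc_inner`` elsewhere labels the
    contexts *after* it as high candidates; symmetrically (``fc_edge`` in
    the last interval) the contexts *before* a jump become low candidates.
    A jump only counts when the greater value exceeds tau_rel, promotions
    require the value itself above tau_rel (demotions: below), conflicts
    revert to moderate, and only entries that are currently moderate ever
    change.
    """
    if len(tpm_profile) != len(categories):
        raise ConfigurationError("TPM profile and category profile differ in length")
    n = len(tpm_profile)
    if n < 2:
        return categories.copy()
    order = np.argsort(tpm_profile.to_numpy(dtype=float), kind="stable")
    vals = tpm_profile.to_numpy(dtype=float)[order] + PSEUDOCOUNT
    logs = np.log2(vals)
    hi_candidate = np.zeros(n, dtype=bool)
    lo_candidate = np.zeros(n, dtype=bool)
    for i in range(n - 1):  # interval between sorted positions i and i+1
        fc = vals[i + 1] / vals[i]
        significant = logs[i + 1] > thresholds.tau_rel
        if significant and fc > (fc_edge if i == 0 else fc_inner):
            hi_candidate[i + 1 :] = True
        if significant and fc > (fc_edge if i == n - 2 else fc_inner):
            lo_candidate[: i + 1] = True
    out = categories.copy()
    for pos in range(n):
        ctx = tpm_profile.index[order[pos]]
        if categories[ctx] != "moderate":
            continue
        if hi_candidate[pos] and lo_candidate[pos]:
            continue  # inconsistently labelled: stays moderate
        if hi_candidate[pos] and logs[pos] > thresholds.tau_rel:
            out[ctx] = "high"
        elif lo_candidate[pos] and logs[pos] < thresholds.tau_rel:
            out[ctx] = "low"
    return out


def recategorize_table(
    tpm: pd.DataFrame,
    categories: pd.DataFrame,
    thresholds: CategorizationThresholds,
    fc_edge: float = 4.0,
    fc_inner: float = 1.5,
) -> pd.DataFrame:
    """Apply the relative pass to every gene with a moderate entry."""
    out = categories.copy()
    moderate_any = (categories == "moderate").any(axis=1)
    for gene in categories.index[moderate_any]:
        out.loc[gene] = recategorize_relative(
            tpm.loc[gene], categories.loc[gene], thresholds, fc_edge=fc_edge, fc_inner=fc_inner
        )
    return out


def categorize(
    tpm: pd.DataFrame,
    seed: int = 0,
    relative: bool = True,
    thresholds: CategorizationThresholds | None = None,
) -> tuple[pd.DataFrame, CategorizationThresholds, GaussianFit | None]:
    """Full categorization: fit thresholds on per-gene mean log2 expression
    across contexts, absolute pass, then the relative pass."""
    fit = None
    if thresholds is None:
        mean_log2 = log2_tpm(tpm).mean(axis=1)
        fit = fit_bimodal(mean_log2, seed=seed)
        thresholds = CategorizationThresholds.from_fit(fit)
    cats = categorize_absolute(tpm, thresholds)
    if relative:
        cats = recategorize_table(tpm, cats, thresholds)
    return cats, thresholds, fit


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_tpm(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.astype(float)


def write_categories(
    categories: pd.DataFrame, path: str | Path, thresholds: CategorizationThresholds | None = None
) -> None:
    long = categories.stack().rename("category").rename_axis(["gene_id", "context"]).reset_index()
    long.to_csv(path, sep="\t", index=False)
    if thresholds is not None:
        thresholds.to_json(Path(path).with_suffix(".thresholds.json"))


def read_categories(path: str | Path) -> pd.DataFrame:
    long = pd.read_csv(path, sep="\t")
    wide = long.pivot(index="gene_id", columns="context", values="category")
    bad = set(np.unique(wide.to_numpy().astype(str))) - set(CATEGORIES)
    if bad:
        raise ConfigurationError(f"unknown categories in {path}: {bad}")
    return wide


def category_lookup(categories: pd.DataFrame, context: str) -> Mapping[str, str]:
    return categories[context].to_dict()
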