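"""Primary/secondary tissue assignment from relative flux potentials.

A target is tissue-enriched when its rFP profile is biased toward one or
two contexts; the top two contexts become the primary and secondary
sites.  Reaction-level calls gain high confidence when the target also
carries flux in the OFD of the primary or secondary tissue (network- and
potential-level evidence agree); metabolite-level calls record OFD
support as a separate flag, because flux minimization deliberately
silences drains and the absence of OFD flux there is not evidence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ConfigurationError

__all__ = ["SiteCallParams", "assign_sites"]


@dataclass
class SiteCallParams:
    """Enrichment rule: call a primary site when max rFP >= min_rfp and
    (top1 - top3)/top1 >= enrichment; a secondary when
    (top2 - top3)/top2 >= enrichment."""

    min_rfp: float = 0.2
    enrichment: float = 0.5


def assign_sites(
    rfp: pd.DataFrame,
    ofd_support: pd.DataFrame | None = None,
    params: SiteCallParams | None = None,
    level: str = "reaction",
) -> pd.DataFrame:
    """Call primary/secondary sites for every target (row) of an rFP matrix.

    ``ofd_support`` is a boolean target x context frame: does the target
    carry OFD flux in that context.  Ties are broken by column order, so
    calls are invariant to reordering only up to equal-rFP ties.
    """
    params = params or SiteCallParams()
    if rfp.shape[1] < 2:
        raise ConfigurationError("need at least two contexts to call sites")
    if level not in ("reaction", "metabolite"):
        raise ConfigurationError(f"unknown level {level!r}")
    rows = []
    for target, profile in rfp.iterrows():
        vals = profile.to_numpy(dtype=float)
        order = np.argsort(-vals, kind="stable")
        top1, top2 = vals[order[0]], vals[order[1]]
        top3 = vals[order[2]] if len(vals) > 2 else 0.0
        primary = secondary = None
        if np.isfinite(top1) and top1 >= params.min_rfp and top1 > 0:
            if (top1 - top3) / top1 >= params.enrichment:
                primary = profile.index[order[0]]
                if top2 > 0 and (top2 - top3) / top2 >= params.enrichment:
                    secondary = profile.index[order[1]]
        supported = False
        if ofd_support is not None and primary is not None:
            called = [c for c in (primary, secondary) if c is not None]
            supported = bool(ofd_support.loc[target, called].any())
        if level == "reaction":
            high_confidence = primary is not None and supported
        else:
            high_confidence = primary is not None
        rows.append(
            {
                "target": target,
                "primary": primary,
                "secondary": secondary,
                "enriched": primary is not None,
                "ofd_supported": supported,
                "high_confidence": high_confidence,
                **{f"rfp_{c}": profile[c] for c in rfp.columns},
            }
        )
    columns = [
        "target",
        "primary",
        "secondary",
        "enriched",
        "ofd_supported",
        "high_confidence",
        *(f"rfp_{c}" for c in rfp.columns),
    ]
    return pd.DataFrame(rows, columns=columns).set_index("target")
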