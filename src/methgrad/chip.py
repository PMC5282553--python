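"""ChIP-qPCR enrichment as percent input with IgG background subtraction.

The input aliquot is a known fraction f of the chromatin that went into the
IP, so its Ct must first be shifted to the full-input scale
(ct_input - log2(1/f)); percent input is then 100 * 2^(adjusted input Ct -
IP Ct).  Background is removed by subtracting the matched IgG percent input,
floored at zero.  The input fraction is a required experimental input and is
never assumed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError, InvalidDesignError
from .gradient_assoc import region_anova, tukey_hsd

CHIP_COLUMNS = ["locus", "segment", "mouse", "ct_ip", "ct_input",
                "input_fraction", "ct_igg"]


def percent_input(ct_ip, ct_input, input_fraction) -> np.ndarray | float:
    """Percent of input chromatin recovered by the IP.

    100 * input_fraction * 2^(ct_input - ct_ip); equivalently
    100 * 2^((ct_input - log2(1/input_fraction)) - ct_ip).  Strictly
    decreasing in ct_ip and strictly increasing in ct_input.
    """
    f = np.asarray(input_fraction, dtype=float)
    if np.any(f <= 0) or np.any(f > 1):
        raise InvalidArgumentError("input_fraction must be in (0, 1]")
    out = 100.0 * f * np.exp2(np.asarray(ct_input, float)
                              - np.asarray(ct_ip, float))
    return float(out) if np.ndim(out) == 0 else out


def background_normalize(target_pct, igg_pct) -> np.ndarray | float:
    """Net percent input: max(0, target - IgG background)."""
    out = np.maximum(0.0, np.asarray(target_pct, float)
                     - np.asarray(igg_pct, float))
    return float(out) if np.ndim(out) == 0 else out


def chip_enrichment(table: pd.DataFrame) -> pd.DataFrame:
    """Add percent_input, percent_input_igg and net_percent_input columns."""
    missing = [c for c in CHIP_COLUMNS if c not in table.columns]
    if missing:
        raise InvalidArgumentError(f"ChIP table lacks columns {missing}")
    out = table.copy()
    out["percent_input"] = percent_input(out["ct_ip"], out["ct_input"],
                                         out["input_fraction"])
    out["percent_input_igg"] = percent_input(out["ct_igg"], out["ct_input"],
                                             out["input_fraction"])
    out["net_percent_input"] = background_normalize(out["percent_input"],
                                                    out["percent_input_igg"])
    return out


@dataclass(eq=False)
class ChipAnovaResult:
    locus: str
    F: float
    p: float
    tukey: pd.DataFrame


def segment_anova(enrichment: pd.DataFrame, locus: str,
                  alpha: float = 0.05) -> ChipAnovaResult:
    """One-way ANOVA of net percent input across intestinal segments."""
    sub = enrichment[enrichment["locus"] == locus]
    if sub.empty:
        raise InvalidDesignError(f"no rows for locus {locus!r}")
    F, p = region_anova(sub["net_percent_input"], sub["segment"])
    tk = tukey_hsd(sub["net_percent_input"], sub["segment"], alpha=alpha)
    return ChipAnovaResult(locus=locus, F=F, p=p, tukey=tk)
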