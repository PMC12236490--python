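"""Limited-proteolysis mass-spectrometry (LiP-MS) peptide-table processing.

Input: per-feature normalized ion counts over six injections (3 replicates x
2 conditions), one row per (peptide, charge state), with missing detections
as NaN. Processing applies the imputation rules, Welch's unequal-variance
t-test per feature, consolidation of charge states, and the significance
gate |log2 ratio| > 1 and -log10 P > 1.3.

Imputation rules:
1. missing in exactly one of the six injections -> keep the feature, drop
   the missing value;
2. missing in more than one injection -> exclude the feature, UNLESS
3. all three replicates of one condition are missing and all three of the
   other are present -> replace the missing triple with the detection limit
   (1000 ion counts).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class LipMsConfig:
    detection_limit: float = 1000.0
    effect_threshold: float = 1.0      # |log2 ratio|
    p_threshold: float = 1.3           # -log10 P
    n_replicates: int = 3

    def __post_init__(self):
        if min(self.detection_limit, self.effect_threshold, self.p_threshold) <= 0:
            raise ValueError("thresholds must be positive")


COND1 = ["cond1_r1", "cond1_r2", "cond1_r3"]
COND2 = ["cond2_r1", "cond2_r2", "cond2_r3"]


def _welch_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Welch t-test; degenerate zero-variance limit handled."""
    if np.var(a) == 0 and np.var(b) == 0:
        return 1.0 if np.mean(a) == np.mean(b) else 0.0
    import warnings
    with warnings.catch_warnings():
        # imputed detection-limit triples are near-identical by construction
        warnings.simplefilter("ignore", RuntimeWarning)
        return float(stats.ttest_ind(a, b, equal_var=False).pvalue)


def impute_feature(c1: np.ndarray, c2: np.ndarray, config: LipMsConfig):
    """Apply the imputation rules to one feature's (cond1, cond2) counts.

    Returns (values1, values2, branch) with branch in {all_present,
    one_missing, condition_missing, excluded}; values are None when excluded.
    """
    m1, m2 = np.isnan(c1), np.isnan(c2)
    total_missing = int(m1.sum() + m2.sum())
    if total_missing == 0:
        return c1, c2, "all_present"
    if total_missing == 1:
        return c1[~m1], c2[~m2], "one_missing"
    if m1.all() and not m2.any():
        return np.full_like(c1, config.detection_limit), c2, "condition_missing"
    if m2.all() and not m1.any():
        return c1, np.full_like(c2, config.detection_limit), "condition_missing"
    return None, None, "excluded"


def lipms_process(table: pd.DataFrame, config: LipMsConfig | None = None):
    """Process a LiP-MS feature table into a significant-peptide report.

    ``table`` columns: ``peptide``, ``charge``, optional ``tryptic``
    ('half' or 'full'), and the six count columns cond1_r1..3, cond2_r1..3.
    Effect sizes are log2(mean cond2 / mean cond1).

    Returns (peptide-level DataFrame, feature-level DataFrame with branch
    labels). Peptide-level p-values combine charge states by Fisher's method
    when effects agree in sign, otherwise the combined p is set to 1; the
    consolidated effect is the median across charge states.
    """
    config = config or LipMsConfig()
    required = {"peptide", "charge", *COND1, *COND2}
    if not required.issubset(table.columns):
        raise ValueError(f"table missing columns {sorted(required - set(table.columns))}")

    feat_rows = []
    for _, row in table.iterrows():
        c1 = row[COND1].to_numpy(dtype=float)
        c2 = row[COND2].to_numpy(dtype=float)
        v1, v2, branch = impute_feature(c1, c2, config)
        rec = {"peptide": row["peptide"], "charge": row["charge"],
               "tryptic": row.get("tryptic", "full"), "branch": branch,
               "log2fc": np.nan, "p": np.nan}
        if branch != "excluded":
            rec["log2fc"] = float(np.log2(np.mean(v2) / np.mean(v1)))
            rec["p"] = _welch_p(v1, v2)
        feat_rows.append(rec)
    features = pd.DataFrame(feat_rows)

    pep_rows = []
    for (pep, tryp), grp in features[features.branch != "excluded"].groupby(
            ["peptide", "tryptic"], sort=False):
        effects = grp["log2fc"].to_numpy()
        ps = grp["p"].to_numpy()
        effect = float(np.median(effects))
        if len(grp) == 1:
            p = float(ps[0])
        elif np.all(effects > 0) or np.all(effects < 0):
            p = float(stats.combine_pvalues(np.clip(ps, 1e-300, 1.0),
                                            method="fisher").pvalue)
        else:
            p = 1.0
        neglog = -np.log10(max(p, 1e-300))
        pep_rows.append({
            "peptide": pep, "tryptic": tryp, "n_charge_states": len(grp),
            "log2fc": effect, "p": p, "neg_log10_p": neglog,
            "significant": bool(abs(effect) > config.effect_threshold
                                and neglog > config.p_threshold)})
    peptides = pd.DataFrame(pep_rows)
    return peptides, features
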