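"""Cognitive phenotyping from neuropsychological domain scores.

Domain scores are Z-scored against the healthy-control sample. A person
with MS is *cognitively impaired* (CI) with two or more domains at
Z <= -2.0, *mildly CI* with two or more domains at -2 < Z <= -1.5 or lower
(evaluated after the CI rule, so any profile meeting the CI criterion is
CI regardless of how many domains sit in the milder band), and
*cognitively preserved* (CP) otherwise. The boundary convention is closed
at the thresholds: Z = -2.0 itself counts toward CI, Z = -1.5 toward
mildly CI. Average cognition is the mean of the available domain Z-scores.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import DOMAINS
from .errors import ConfigError, UnclassifiableError

CI_THRESHOLD = -2.0
MILD_THRESHOLD = -1.5
MIN_DOMAINS = 2

SCORE_COLUMNS = [f"score_{d}" for d in DOMAINS]
Z_COLUMNS = [f"domain_z_{d}" for d in DOMAINS]


def fit_domain_reference(hc_scores: pd.DataFrame) -> pd.DataFrame:
    """Per-domain HC mean and SD (ddof=1) from raw test scores.

    ``hc_scores`` holds one column per domain (``score_<domain>``).
    """
    cols = [c for c in SCORE_COLUMNS if c in hc_scores.columns]
    if len(cols) != len(DOMAINS):
        missing = set(SCORE_COLUMNS) - set(cols)
        raise ConfigError(f"missing domain score columns: {sorted(missing)}")
    ref = pd.DataFrame(
        {
            "mean": hc_scores[cols].mean(),
            "sd": hc_scores[cols].std(ddof=1),
        }
    )
    ref.index = [c.removeprefix("score_") for c in cols]
    if (ref["sd"] <= 0).any():
        bad = list(ref.index[ref["sd"] <= 0])
        raise ConfigError(f"zero HC SD for domains {bad}; cannot Z-score")
    return ref


def domain_zscores(
    test_scores: pd.Series | pd.DataFrame, hc_reference: pd.DataFrame
) -> pd.Series | pd.DataFrame:
    """(score - hc_mean) / hc_sd per domain; missing scores stay missing."""
    single = isinstance(test_scores, pd.Series)
    frame = test_scores.to_frame().T if single else test_scores
    out = {}
    for d in DOMAINS:
        col = f"score_{d}"
        out[f"domain_z_{d}"] = (frame[col] - hc_reference.loc[d, "mean"]) / (
            hc_reference.loc[d, "sd"]
        )
    z = pd.DataFrame(out, index=frame.index)
    return z.iloc[0] if single else z


def classify_phenotype(domain_z) -> str:
    """Apply the CI / mildly CI / CP rule to a 7-domain Z vector.

    Requires at least :data:`MIN_DOMAINS` non-missing domains; evaluation
    order is CI first, then mildly CI, then CP.
    """
    z = np.asarray(pd.Series(domain_z).to_numpy(), dtype=float)
    avail = z[~np.isnan(z)]
    if avail.size < MIN_DOMAINS:
        raise UnclassifiableError(
            f"only {avail.size} available domains; need >= {MIN_DOMAINS}"
        )
    if (avail <= CI_THRESHOLD).sum() >= 2:
        return "CI"
    if (avail <= MILD_THRESHOLD).sum() >= 2:
        return "mildly_CI"
    return "CP"


def average_cognition(domain_z) -> float:
    """Arithmetic mean of the available domain Z-scores (NaN if none)."""
    z = pd.Series(domain_z).astype(float)
    avail = z.dropna()
    return float(avail.mean()) if len(avail) else float("nan")


def label_cohort(cohort: pd.DataFrame, hc_reference: pd.DataFrame) -> pd.DataFrame:
    """Add ``domain_z_*``, ``avg_cog_z`` and ``phenotype`` columns.

    HC subjects keep the label ``"HC"``; MS subjects are classified by the
    rule above. Unclassifiable subjects (too many missing domains) get a
    missing phenotype.
    """
    out = cohort.copy()
    z = domain_zscores(out[SCORE_COLUMNS], hc_reference)
    for c in z.columns:
        out[c] = z[c]
    out["avg_cog_z"] = z.mean(axis=1, skipna=True)
    out["n_missing_domains"] = z.isna().sum(axis=1)

    labels = []
    for subj, row in out.iterrows():
        if row["group"] == "HC":
            labels.append("HC")
            continue
        try:
            labels.append(classify_phenotype(row[Z_COLUMNS]))
        except UnclassifiableError:
            labels.append(pd.NA)
    out["phenotype"] = labels
    return out
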