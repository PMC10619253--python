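"""Sample/taxon filtering and compositional transforms.

Count tables are plain pandas DataFrames: rows = samples, columns = genera,
non-negative integer entries. Two zero-handling strategies coexist because the
analysis uses them on different paths: multiplicative replacement (zeros get a
small delta, nonzero parts rescaled so the composition still closes to 1)
feeds the Pearson correlation network, while a pseudo-count of 1 feeds the
keystone-index CLR.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "filter_samples",
    "filter_prevalence",
    "multiplicative_impute",
    "clr_transform",
]

DEFAULT_MIN_DEPTH = 5000
DEFAULT_MIN_PREVALENCE = 0.10


def _check_table(table: pd.DataFrame) -> None:
    if table.index.has_duplicates or table.columns.has_duplicates:
        raise ValueError("count table has duplicate sample or taxon ids")
    if (table.to_numpy() < 0).any():
        raise ValueError("count table has negative entries")


def filter_samples(
    table: pd.DataFrame,
    metadata: pd.DataFrame,
    min_depth: int = DEFAULT_MIN_DEPTH,
    require_birth_year: bool = True,
    exclude_antibiotics: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the cohort inclusion criteria; return (table, exclusion log).

    A sample is retained when its sequencing depth is >= ``min_depth``
    (default 5000; depth read from metadata column ``depth`` when present,
    otherwise the table row sum), its birth year is known (when
    ``require_birth_year``), and it has no recent antibiotic use (metadata
    column ``antibiotics``, when ``exclude_antibiotics``).

    The log records exactly one reason per excluded sample, checked in the
    order depth, birth year, antibiotics.
    """
    _check_table(table)
    missing = table.index.difference(metadata.index)
    if len(missing):
        raise ValueError(f"metadata missing for samples: {list(missing)[:5]}")

    meta = metadata.loc[table.index]
    depth = (
        meta["depth"] if "depth" in meta.columns else table.sum(axis=1)
    ).astype(float)

    reasons: dict[str, str] = {}
    for sid in table.index:
        if depth.loc[sid] < min_depth:
            reasons[sid] = f"depth < {min_depth}"
        elif require_birth_year and (
            "birth_year" not in meta.columns or pd.isna(meta.loc[sid, "birth_year"])
        ):
            reasons[sid] = "missing birth year"
        elif exclude_antibiotics and "antibiotics" in meta.columns and bool(
            meta.loc[sid, "antibiotics"]
        ):
            reasons[sid] = "recent antibiotic use"

    keep = [sid for sid in table.index if sid not in reasons]
    log = pd.DataFrame(
        {"sample_id": list(reasons), "reason": list(reasons.values())}
    )
    if not keep:
        dominant = log["reason"].mode().iloc[0] if len(log) else "no samples"
        raise ValueError(
            f"all samples excluded; dominant exclusion reason: {dominant}"
        )
    return table.loc[keep], log


def filter_prevalence(
    table: pd.DataFrame, min_prevalence: float = DEFAULT_MIN_PREVALENCE
) -> pd.DataFrame:
    """Drop rare taxa: retain taxa present (count > 0) in >= ``min_prevalence``
    of samples. The boundary is retained — exactly 10% prevalence survives the
    default "< 10%" rule. Samples are never dropped here.
    """
    if not 0 <= min_prevalence <= 1:
        raise ValueError("min_prevalence must be in [0, 1]")
    if table.shape[0] == 0:
        raise ValueError("empty count table")
    prevalence = (table > 0).mean(axis=0)
    return table.loc[:, prevalence >= min_prevalence]


def multiplicative_impute(
    table: pd.DataFrame, delta_rule: str = "bdl-0.65"
) -> pd.DataFrame:
    """Multiplicative zero replacement; returns strictly positive compositions.

    Per sample, zeros are replaced by a small delta on the relative-abundance
    scale and the nonzero parts are rescaled by (1 - total imputed mass), so
    each row still sums to 1 and ratios among originally nonzero parts are
    preserved. The default rule ``bdl-0.65`` sets delta to 0.65 x the sample's
    smallest nonzero relative abundance (a below-detection-limit convention).
    """
    if delta_rule != "bdl-0.65":
        raise ValueError(f"unknown delta_rule {delta_rule!r}")
    x = table.to_numpy(dtype=float)
    depth = x.sum(axis=1)
    if (depth <= 0).any():
        bad = table.index[depth <= 0].tolist()
        raise ValueError(
            f"all-zero samples {bad[:5]}: filter samples before imputation"
        )
    rel = x / depth[:, None]
    out = np.empty_like(rel)
    for i in range(rel.shape[0]):
        row = rel[i]
        zero = row == 0
        if not zero.any():
            out[i] = row
            continue
        delta = 0.65 * row[row > 0].min()
        imputed_mass = delta * zero.sum()
        out[i] = np.where(zero, delta, row * (1.0 - imputed_mass))
    return pd.DataFrame(out, index=table.index, columns=table.columns)


def clr_transform(
    data: pd.DataFrame, pseudocount: float | None = None
) -> pd.DataFrame:
    """Centered log-ratio transform: log(x_ij) - mean_k log(x_ik) per sample.

    With ``pseudocount`` set, it is added to the raw counts before closure
    (the keystone-index convention uses pseudocount 1). Without it, the input
    must already be a strictly positive composition (e.g. output of
    :func:`multiplicative_impute`). Output rows sum to zero.
    """
    x = data.to_numpy(dtype=float)
    if pseudocount is not None:
        if pseudocount <= 0:
            raise ValueError("pseudocount must be positive")
        x = x + pseudocount
        x = x / x.sum(axis=1, keepdims=True)
    elif (x <= 0).any():
        raise ValueError(
            "nonpositive entries: pass a positive composition or set a pseudocount"
        )
    logx = np.log(x)
    clr = logx - logx.mean(axis=1, keepdims=True)
    return pd.DataFrame(clr, index=data.index, columns=data.columns)
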