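"""Structural anisotropy (FA/QA) ingestion and group comparison.

Fiber tracking itself is out of scope: fractional anisotropy (FA) and
quantitative anisotropy (QA) arrive as one scalar per (subject, connection),
the form in which tractography exports are consumed statistically.  The
tracking parameter table (per-connection length window, angular threshold
and QA threshold) ships as reference metadata for validating external
exports; it plays no computational role.
"""

from __future__ import annotations

import logging
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .atlas import Connection
from .errors import SizingError, ValidationError
from .groupstats import compare_groups

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("subject_id", "connection", "fa", "qa")


def load_tracking_parameters() -> pd.DataFrame:
    """Per-connection deterministic-tracking parameters (reference metadata)."""
    with resources.files("streamconn.data").joinpath("tracking_parameters.csv").open() as fh:
        table = pd.read_csv(fh)
    bad = table[table["min_length_mm"] >= table["max_length_mm"]]
    if not bad.empty:
        raise ValidationError("tracking parameters: min_length must be < max_length")
    return table


def load_structural_table(
    source,
    roster: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Validated per-subject, per-connection FA/QA records.

    ``source`` is a CSV path or a DataFrame with columns
    ``subject_id, connection, fa, qa``.  FA must lie in (0, 1) and QA must be
    positive (offending rows are reported); duplicate (subject, connection)
    rows are rejected.  When a roster with completeness flags is given,
    subjects with incomplete tractography are excluded with a logged count.
    """
    table = source.copy() if isinstance(source, pd.DataFrame) else pd.read_csv(source)
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"structural table is missing columns {missing}")
    if table.empty:
        return table
    bad_fa = table[(table["fa"] <= 0) | (table["fa"] >= 1)]
    if not bad_fa.empty:
        raise ValidationError(
            f"FA outside (0, 1) at rows {bad_fa.index.tolist()[:20]}"
        )
    bad_qa = table[table["qa"] <= 0]
    if not bad_qa.empty:
        raise ValidationError(f"QA must be > 0; bad rows {bad_qa.index.tolist()[:20]}")
    dup = table.duplicated(subset=["subject_id", "connection"])
    if dup.any():
        raise ValidationError(
            f"duplicate (subject, connection) rows at {table.index[dup].tolist()[:20]}"
        )
    if roster is not None:
        incomplete = set(roster.loc[~roster["tract_complete"], "subject_id"])
        before = table["subject_id"].nunique()
        table = table[~table["subject_id"].isin(incomplete)]
        after = table["subject_id"].nunique()
        if before != after:
            logger.info("excluded %d subjects with incomplete tractography", before - after)
    return table.reset_index(drop=True)


def structural_group_comparison(
    records: pd.DataFrame,
    families: Mapping[str, Sequence[Connection]],
    roster: pd.DataFrame,
    alternative: str = "two-sided",
) -> pd.DataFrame:
    """Wilcoxon + Holm comparison of FA and QA, per connection, per family.

    Routes through the same statistical engine as the functional
    comparisons; FA and QA are tested separately (connections x 2 rows).
    """
    if records.empty:
        raise SizingError("structural table is empty")
    out = []
    for metric in ("fa", "qa"):
        long = records.melt(
            id_vars=["subject_id", "connection"],
            value_vars=[metric],
            var_name="metric",
            value_name="value",
        )
        long["direction"] = "undirected"
        out.append(
            compare_groups(long, metric, families, roster, alternative=alternative)
        )
    return pd.concat(out, ignore_index=True)
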