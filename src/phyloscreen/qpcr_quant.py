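"""Comparative-Ct quantification of qPCR measurements.

Raw cycle-threshold (Ct) values are collapsed over technical replicates,
normalized against the mean Ct of a set of reference genes, and expressed
relative to a calibrator condition as 2**(-ddCt).
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = ["CT_COLUMNS", "MissingReferenceError", "collapse_technical",
           "delta_delta_ct"]

CT_COLUMNS = ("gene", "condition", "bio_rep", "tech_rep", "ct")


class MissingReferenceError(KeyError):
    """A (gene, condition, bio_rep) key lacks a reference-gene Ct."""


def _check_ct_frame(records: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CT_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"Ct table missing columns: {missing}")
    if not np.isfinite(records["ct"].to_numpy(dtype=float)).all():
        raise ValueError("Ct values must be finite")
    dup = records.duplicated(subset=["gene", "condition", "bio_rep", "tech_rep"])
    if dup.any():
        first = records[dup].iloc[0]
        raise ValueError(
            "duplicate Ct record for "
            f"({first['gene']}, {first['condition']}, {first['bio_rep']}, "
            f"{first['tech_rep']})")
    return records


def collapse_technical(records: pd.DataFrame) -> pd.DataFrame:
    """Mean Ct per (gene, condition, bio_rep), with the technical count.

    Returns a frame with columns gene, condition, bio_rep, ct, n_tech.
    """
    _check_ct_frame(records)
    grouped = (records.groupby(["gene", "condition", "bio_rep"], sort=True)
               ["ct"].agg(ct="mean", n_tech="count").reset_index())
    return grouped


def delta_delta_ct(
    ct_means: pd.DataFrame,
    reference_genes: Iterable[str],
    calibrator: str,
) -> pd.DataFrame:
    """Relative expression by the comparative-Ct (2**-ddCt) method.

    dCt = Ct_target - mean(Ct of the reference genes) within each
    (condition, bio_rep); ddCt = dCt - mean(dCt over the calibrator
    condition's biological replicates); value = 2**(-ddCt). Reference
    genes are consumed for normalization and not reported.
    """
    refs = sorted(set(reference_genes))
    if not refs:
        raise ValueError("at least one reference gene required")
    for col in ("gene", "condition", "bio_rep", "ct"):
        if col not in ct_means.columns:
            raise ValueError(f"ct_means missing column {col!r}")
    if calibrator not in set(ct_means["condition"]):
        raise ValueError(f"calibrator condition {calibrator!r} not present")

    ref_rows = ct_means[ct_means["gene"].isin(refs)]
    ref_ct = (ref_rows.groupby(["condition", "bio_rep"])["ct"]
              .agg(["mean", "count"]))
    targets = ct_means[~ct_means["gene"].isin(refs)].copy()

    keys = targets.set_index(["condition", "bio_rep"]).index
    for key in keys.unique():
        if key not in ref_ct.index or ref_ct.loc[key, "count"] < len(refs):
            raise MissingReferenceError(
                f"missing reference-gene Ct for (condition, bio_rep)={key}")

    targets["dct"] = (targets["ct"].to_numpy()
                      - ref_ct["mean"].reindex(keys).to_numpy())
    cal_mean = (targets[targets["condition"] == calibrator]
                .groupby("gene")["dct"].mean())
    missing_cal = set(targets["gene"]) - set(cal_mean.index)
    if missing_cal:
        raise MissingReferenceError(
            f"no calibrator measurements for genes: {sorted(missing_cal)}")
    targets["ddct"] = targets["dct"] - cal_mean.reindex(targets["gene"]).to_numpy()
    targets["value"] = 2.0 ** (-targets["ddct"])
    out = targets[["gene", "condition", "bio_rep", "value"]].reset_index(drop=True)
    return out


def relative_expression_by_condition(
    rel: pd.DataFrame,
    conditions: Sequence[str] | None = None,
) -> dict[str, dict[str, np.ndarray]]:
    """Pivot a relative-expression frame into gene -> condition -> values."""
    out: dict[str, dict[str, np.ndarray]] = {}
    for (gene, cond), grp in rel.groupby(["gene", "condition"]):
        if conditions is not None and cond not in conditions:
            continue
        out.setdefault(gene, {})[cond] = grp["value"].to_numpy(dtype=float)
    return out
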