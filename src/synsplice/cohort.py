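"""Training-cohort construction: filters, balancing, splitting, accounting.

A cohort is a pandas DataFrame with one row per variant and at least the
columns

    variant_id, label ('disease'|'neutral'), site_class ('VSS'|'VIE'),
    exon_id, exon_index, n_exons, maf, category

``category`` carries the disease-database evidence tier for positives
(DM = disease-causing, DM? = likely, FP = functional polymorphism,
DP/DFP = disease-associated) and may be empty for neutrals.

Filters mirror the training-set construction of the method: variants in a
gene's first or last exon are removed (their inclusion is governed by
promoter/polyadenylation choice rather than splicing), at most one variant
is kept per exon, and neutral variants must exceed a minor-allele-frequency
floor (strictly greater than 3% for VSS, 10% for VIE). Balancing
downsamples neutrals to the positive count and the train/test split is
stratified by label with exon-disjoint partitions.
"""

from __future__ import annotations

import logging
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ClassEmpty

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = (
    "variant_id",
    "label",
    "site_class",
    "exon_id",
    "exon_index",
    "n_exons",
    "maf",
)

VSS_MAF_MIN = 0.03
VIE_MAF_MIN = 0.10
CATEGORIES = ("DM", "DM?", "FP", "DP/DFP")


def _check(df: pd.DataFrame):
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort is missing columns {missing}")


def apply_filters(
    raw: pd.DataFrame,
    vss_maf_min: float = VSS_MAF_MIN,
    vie_maf_min: float = VIE_MAF_MIN,
    seed: Optional[int] = None,
    dedup: str = "random",
    exclude_ids=None,
) -> pd.DataFrame:
    """Apply the training-set filters; idempotent for a fixed seed policy.

    Order: optional exclusion list (e.g. overlap with an external clinical
    database), first/last-exon removal, one-variant-per-exon
    de-duplication (``dedup='random'`` seeded, or ``'first'`` = smallest
    position for reproducible pipelines), then the strict MAF floors for
    neutral variants (variants with missing MAF are kept with a warning).
    """
    _check(raw)
    df = raw.copy()

    if exclude_ids is not None:
        df = df[~df["variant_id"].isin(set(exclude_ids))]

    internal = (df["exon_index"] > 0) & (df["exon_index"] < df["n_exons"] - 1)
    df = df[internal]

    if dedup == "random":
        rng = np.random.default_rng(seed)
        keep_idx = []
        for _exon, grp in df.groupby("exon_id", sort=True):
            keep_idx.append(rng.choice(grp.index.to_numpy()))
        df = df.loc[sorted(keep_idx, key=list(df.index).index)]
    elif dedup == "first":
        if "pos" in df.columns:
            df = df.sort_values(["exon_id", "pos"], kind="stable")
        df = df.groupby("exon_id", sort=False).head(1)
    else:
        raise ValueError(f"unknown dedup mode {dedup!r}")

    neutral = df["label"] == "neutral"
    maf = df["maf"]
    n_missing = int((neutral & maf.isna()).sum())
    if n_missing:
        logger.warning(
            "%d neutral variants have no MAF; frequency floor not applied to them",
            n_missing,
        )
    floor = np.where(df["site_class"] == "VSS", vss_maf_min, vie_maf_min)
    fails = neutral & maf.notna() & ~(maf > floor)
    df = df[~fails]

    return df.reset_index(drop=True)


def balance_and_split(
    cohort: pd.DataFrame,
    train_frac: float = 2.0 / 3.0,
    seed: Optional[int] = None,
):
    """Balance classes then split into train/test, stratified by label.

    Neutrals are downsampled (seeded, without replacement) to the positive
    count; each class is then split at ``train_frac`` (round-to-nearest on
    the train side). Exon disjointness between partitions follows from the
    one-variant-per-exon invariant and is asserted.
    """
    _check(cohort)
    pos = cohort[cohort["label"] == "disease"]
    neg = cohort[cohort["label"] == "neutral"]
    if len(pos) == 0 or len(neg) == 0:
        raise ClassEmpty(
            f"both classes required: {len(pos)} disease / {len(neg)} neutral"
        )
    rng = np.random.default_rng(seed)
    if len(neg) > len(pos):
        keep = rng.choice(neg.index.to_numpy(), size=len(pos), replace=False)
        neg = neg.loc[np.sort(keep)]

    def _split(grp: pd.DataFrame):
        idx = grp.index.to_numpy().copy()
        rng.shuffle(idx)
        n_train = int(round(len(idx) * train_frac))
        return grp.loc[np.sort(idx[:n_train])], grp.loc[np.sort(idx[n_train:])]

    pos_tr, pos_te = _split(pos)
    neg_tr, neg_te = _split(neg)
    train = pd.concat([pos_tr, neg_tr]).reset_index(drop=True)
    test = pd.concat([pos_te, neg_te]).reset_index(drop=True)

    shared = set(train["exon_id"]) & set(test["exon_id"])
    if shared:
        raise AssertionError(f"train/test share exons: {sorted(shared)[:5]}")
    return train, test


def category_fractions(cohort: pd.DataFrame, site_class: str) -> dict:
    """Percentage of each evidence category among positives of a site class.

    Percentages are rounded to one decimal, matching how such breakdowns
    are conventionally reported.
    """
    pos = cohort[(cohort["label"] == "disease") & (cohort["site_class"] == site_class)]
    if len(pos) == 0:
        return {}
    counts = pos["category"].value_counts()
    total = len(pos)
    return {
        str(cat): round(100.0 * n / total, 1) for cat, n in counts.items()
    }


def cohort_from_counts(category_counts: dict, site_class: str) -> pd.DataFrame:
    """Expand a {category: count} table into a minimal positive cohort.

    Convenience for category accounting when only printed per-category
    counts are available rather than variant-level records.
    """
    rows = []
    i = 0
    for cat, n in category_counts.items():
        for _ in range(int(n)):
            rows.append(
                {
                    "variant_id": f"{site_class.lower()}_{i}",
                    "label": "disease",
                    "site_class": site_class,
                    "exon_id": f"exon_{site_class}_{i}",
                    "exon_index": 1,
                    "n_exons": 3,
                    "maf": np.nan,
                    "category": cat,
                }
            )
            i += 1
    return pd.DataFrame(rows)
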