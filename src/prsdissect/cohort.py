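"""Longitudinal diagnosis handling and the four case/control contrasts.

A subject's visit-level diagnoses (CN/MCI/AD) are collapsed into one
analysis label by their (first, last) diagnosis pair: stable subjects keep
their diagnosis; MCI-to-AD converters are analysed as MCI with a converter
flag (the convention of longitudinal AD cohorts, where the conversion
itself is the outcome of interest); AD-to-MCI reverters are analysed as
MCI; CN-to-MCI and MCI-to-CN trajectories are excluded.  Amyloid status is
a threshold on the latest PET SUVR (AV45 cutoff 1.11, inclusive).

The four contrasts built from these labels are: AD vs control, MCI vs
control, amyloid-positive vs amyloid-negative, and — among amyloid-positive
subjects with baseline MCI — converters vs non-converters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

SUVR_THRESHOLD = 1.11

CONTROL, MCI, AD, EXCLUDE = "CONTROL", "MCI", "AD", "EXCLUDE"
POSITIVE, NEGATIVE, MISSING = "POSITIVE", "NEGATIVE", "MISSING"

#: (first, last) diagnosis pair -> analysis label
_TRAJECTORY = {
    ("CN", "CN"): CONTROL,
    ("MCI", "MCI"): MCI,
    ("AD", "AD"): AD,
    ("CN", "MCI"): EXCLUDE,
    ("MCI", "CN"): EXCLUDE,
    ("MCI", "AD"): MCI,  # converter, flagged separately
    ("AD", "MCI"): MCI,
    ("CN", "AD"): AD,  # rapid converter: analysed by last diagnosis
    ("AD", "CN"): EXCLUDE,
}


def classify_trajectory(visits: pd.DataFrame, converters_as: str = "MCI") -> pd.DataFrame:
    """Collapse visit-level diagnoses into one analysis label per subject.

    ``visits`` needs columns IID, VISIT, DX.  Non-monotone paths are
    resolved by the (first, last) diagnosis pair.  ``converters_as="MCI"``
    keeps MCI-to-AD converters in the MCI arm with ``converter=True``
    (default); ``converters_as="AD"`` labels them by their last diagnosis
    instead.

    Returns a frame with IID, LABEL, BASELINE_DX, FINAL_DX, CONVERTER.
    """
    if converters_as not in ("MCI", "AD"):
        raise ValueError("converters_as must be 'MCI' or 'AD'")
    if visits.empty:
        raise ValueError("empty visit table")
    bad = set(visits["DX"].unique()) - {"CN", "MCI", "AD"}
    if bad:
        raise ValueError(f"unknown diagnosis code(s): {sorted(bad)}")
    ordered = visits.sort_values(["IID", "VISIT"], kind="mergesort")
    first = ordered.groupby("IID", sort=True)["DX"].first()
    last = ordered.groupby("IID", sort=True)["DX"].last()
    # converter: baseline MCI and AD at any later visit
    saw_ad = ordered[ordered["DX"] == "AD"].groupby("IID")["VISIT"].min()
    rows = []
    n_conv_relabelled = 0
    for iid in first.index:
        pair = (first[iid], last[iid])
        label = _TRAJECTORY[pair]
        converter = bool(first[iid] == "MCI" and iid in saw_ad.index)
        if converter and converters_as == "AD":
            label = AD
            n_conv_relabelled += 1
        rows.append((iid, label, pair[0], pair[1], converter))
    if converters_as == "MCI":
        n_conv = sum(r[4] for r in rows)
        if n_conv:
            log.warning(
                "%d MCI-to-AD converters analysed in the MCI arm (trajectory "
                "convention); pass converters_as='AD' for last-diagnosis labelling",
                n_conv,
            )
    return pd.DataFrame(rows, columns=["IID", "LABEL", "BASELINE_DX", "FINAL_DX", "CONVERTER"])


def assign_amyloid(cohort: pd.DataFrame, threshold: float = SUVR_THRESHOLD) -> pd.DataFrame:
    """Amyloid status from the latest available SUVR per subject.

    Status is POSITIVE iff SUVR >= threshold (inclusive), NEGATIVE below,
    MISSING when no scan is recorded.  Negative SUVR values are an error.

    Returns a frame with IID, SUVR, AMYLOID.
    """
    if "SUVR" not in cohort.columns:
        raise ValueError("cohort has no SUVR column")
    valid = cohort.dropna(subset=["SUVR"])
    if (valid["SUVR"] < 0).any():
        raise ValueError("negative SUVR value")
    latest = (
        valid.sort_values(["IID", "VISIT"], kind="mergesort").groupby("IID", sort=True)["SUVR"].last()
    )
    all_ids = pd.Index(sorted(cohort["IID"].unique()))
    suvr = latest.reindex(all_ids)
    status = np.where(suvr.isna(), MISSING, np.where(suvr >= threshold, POSITIVE, NEGATIVE))
    return pd.DataFrame({"IID": all_ids, "SUVR": suvr.to_numpy(), "AMYLOID": status})


@dataclass
class Contrast:
    """One case/control framing: subject ids and binary outcome."""

    name: str
    ids: np.ndarray
    y: np.ndarray  # 1 = case

    @property
    def n_case(self) -> int:
        return int(self.y.sum())

    @property
    def n_control(self) -> int:
        return int(len(self.y) - self.y.sum())


def build_contrasts(labels: pd.DataFrame, amyloid: pd.DataFrame) -> dict[str, Contrast]:
    """Build the four analysis contrasts from labels and amyloid status.

    1. ``ad``          — AD vs CONTROL
    2. ``mci``         — MCI vs CONTROL
    3. ``amyloid``     — amyloid POSITIVE vs NEGATIVE (all labels; MISSING dropped)
    4. ``conversion``  — among amyloid-positive subjects with baseline MCI,
       MCI-to-AD converters vs non-converters.

    EXCLUDE subjects enter no contrast.  Any empty arm is an error.
    """
    merged = labels.merge(amyloid, on="IID", how="left")
    merged["AMYLOID"] = merged["AMYLOID"].fillna(MISSING)
    keep = merged[merged["LABEL"] != EXCLUDE]

    def _make(name, frame, case_mask) -> Contrast:
        y = case_mask.to_numpy().astype(float)
        c = Contrast(name=name, ids=frame["IID"].to_numpy(), y=y)
        if c.n_case == 0 or c.n_control == 0:
            raise ValueError(f"contrast {name!r} has an empty arm ({c.n_case} cases, {c.n_control} controls)")
        log.info("contrast %s: %d cases / %d controls", name, c.n_case, c.n_control)
        return c

    ad_frame = keep[keep["LABEL"].isin([AD, CONTROL])]
    mci_frame = keep[keep["LABEL"].isin([MCI, CONTROL])]
    amy_frame = keep[keep["AMYLOID"].isin([POSITIVE, NEGATIVE])]
    conv_frame = keep[(keep["BASELINE_DX"] == "MCI") & (keep["AMYLOID"] == POSITIVE)]

    return {
        "ad": _make("ad", ad_frame, ad_frame["LABEL"] == AD),
        "mci": _make("mci", mci_frame, mci_frame["LABEL"] == MCI),
        "amyloid": _make("amyloid", amy_frame, amy_frame["AMYLOID"] == POSITIVE),
        "conversion": _make("conversion", conv_frame, conv_frame["CONVERTER"]),
    }


def write_labels(labels: pd.DataFrame, amyloid: pd.DataFrame, path) -> None:
    """Emit the labels TSV (IID, LABEL, CONVERTER, AMYLOID, SUVR)."""
    out = labels.merge(amyloid, on="IID", how="left")
    out[["IID", "LABEL", "CONVERTER", "AMYLOID", "SUVR"]].to_csv(path, sep="\t", index=False, na_rep="NA")
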