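"""qPCR quantification: MeDIP percent recovery and ddCt relative expression.

Two outcome scales are produced from raw cycle-threshold (Ct) measurements:

* **Percent recovery** for methylated-DNA immunoprecipitation (MeDIP) assays:
  the fraction of input DNA recovered by the 5-methylcytosine antibody,
  ``2**(ct_in - 3.32 - ct_ip) * 100``.  The constant 3.32 (= log2 10) corrects
  for the input aliquot holding 10% of the material.

* **Relative quantity (RQ)** for gene expression via the ddCt method:
  dCt = Ct(target) - Ct(reference gene); the calibrator is the mean control
  dCt per gene, so RQ = 2**-(dCt - calibrator) and the control group's
  geometric-mean RQ is exactly 1.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError

# log2(10): dilution correction for a 10% input aliquot
INPUT_DILUTION_FACTOR = 3.32

METHYLATION_LOCI = ("global", "CNOT2", "DPP6", "FOXG1", "NPTX2")
EXPRESSION_GENES = ("DNMT1", "DNMT3a", "DNMT3b")


@dataclass(frozen=True)
class CtRecord:
    """One MeDIP-qPCR measurement: input-aliquot and immunoprecipitated Ct."""

    sample_id: str
    ct_in: float
    ct_ip: float
    locus: str = "global"

    def __post_init__(self) -> None:
        for field in ("ct_in", "ct_ip"):
            v = getattr(self, field)
            if not math.isfinite(v) or v <= 0:
                raise InputError(f"{field} must be finite and > 0, got {v!r}")


@dataclass(frozen=True)
class ExpressionCtRecord:
    """One expression measurement: target-gene and reference-gene Ct."""

    sample_id: str
    gene: str
    ct_target: float
    ct_reference: float
    group: int | None = None

    def __post_init__(self) -> None:
        for field in ("ct_target", "ct_reference"):
            v = getattr(self, field)
            if not math.isfinite(v) or v <= 0:
                raise InputError(f"{field} must be finite and > 0, got {v!r}")


def percent_recovery(ct_in, ct_ip):
    """Immunoprecipitation percent recovery from input and IP Ct values.

    Accepts scalars or arrays.  Strictly increasing in ``ct_in`` and strictly
    decreasing in ``ct_ip``; always positive.  Values above 100% are possible
    (e.g. loci enriched beyond the input aliquot) and are passed through.
    """
    ct_in = np.asarray(ct_in, dtype=float)
    ct_ip = np.asarray(ct_ip, dtype=float)
    if not (np.all(np.isfinite(ct_in)) and np.all(np.isfinite(ct_ip))):
        raise InputError("percent_recovery requires finite Ct values")
    out = np.exp2(ct_in - INPUT_DILUTION_FACTOR - ct_ip) * 100.0
    return float(out) if out.ndim == 0 else out


def relative_expression(
    records: list[ExpressionCtRecord], control_ids: set[str]
) -> pd.DataFrame:
    """ddCt relative quantities, calibrated to the control-group mean dCt.

    Parameters
    ----------
    records
        One record per (sample, gene).  Duplicates are rejected; average
        technical replicates upstream (see :func:`read_plate_csv`).
    control_ids
        Sample ids forming the calibrator group; every gene must have at
        least one control record.

    Returns
    -------
    DataFrame with columns ``sample_id, gene, dct, rq``; within each gene the
    geometric mean of the control RQs is 1.
    """
    if not control_ids:
        raise ConfigurationError("control_ids must be non-empty")
    if not records:
        raise InputError("no expression records supplied")
    df = pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in records],
            "gene": [r.gene for r in records],
            "dct": [r.ct_target - r.ct_reference for r in records],
        }
    )
    dup = df.duplicated(["sample_id", "gene"])
    if dup.any():
        pairs = df.loc[dup, ["sample_id", "gene"]].itertuples(index=False)
        raise InputError(
            "duplicate (sample, gene) records: "
            + ", ".join(f"({s}, {g})" for s, g in pairs)
        )
    present = set(df["sample_id"])
    missing = control_ids - present
    if missing == control_ids:
        raise ConfigurationError(
            f"none of the control ids {sorted(control_ids)} appear in the records"
        )
    out = []
    for gene, sub in df.groupby("gene", sort=False):
        controls = sub[sub["sample_id"].isin(control_ids)]
        if controls.empty:
            raise ConfigurationError(f"gene {gene!r} has no control records")
        calibrator = controls["dct"].mean()
        rq = np.exp2(-(sub["dct"] - calibrator))
        out.append(sub.assign(rq=rq))
    return pd.concat(out, ignore_index=True)


def read_plate_csv(path) -> pd.DataFrame:
    """Read a plate table (columns sample_id, assay, role, ct).

    ``role`` is ``input``/``ip`` for methylation assays and
    ``target``/``reference`` for expression assays.  Technical replicate
    wells sharing (sample_id, assay, role) are averaged.
    """
    df = pd.read_csv(path)
    required = {"sample_id", "assay", "role", "ct"}
    missing = required - set(df.columns)
    if missing:
        raise InputError(f"plate CSV missing columns: {sorted(missing)}")
    bad = set(df["role"]) - {"input", "ip", "target", "reference"}
    if bad:
        raise InputError(f"unknown plate roles: {sorted(bad)}")
    return (
        df.groupby(["sample_id", "assay", "role"], as_index=False)["ct"]
        .mean()
    )


def quantify_plate(
    plate: pd.DataFrame, control_ids: set[str] | None = None
) -> pd.DataFrame:
    """Turn a (replicate-averaged) plate table into per-sample outcomes.

    Methylation assays (roles input/ip) become ``<assay>`` percent-recovery
    columns; expression assays (roles target/reference) become relative
    quantities calibrated on ``control_ids``.  Returns one row per sample,
    joinable onto a cohort table.
    """
    wide = plate.pivot_table(
        index=["sample_id", "assay"], columns="role", values="ct", aggfunc="mean"
    ).reset_index()
    outcomes: dict[str, dict[str, float]] = {}

    meth = wide.dropna(subset=["input", "ip"]) if "input" in wide and "ip" in wide else None
    if meth is not None and not meth.empty:
        rec = percent_recovery(meth["input"].to_numpy(), meth["ip"].to_numpy())
        n_high = int(np.sum(rec > 100.0))
        if n_high:
            warnings.warn(
                f"{n_high} percent-recovery value(s) exceed 100%; "
                "passed through uncapped",
                RuntimeWarning,
                stacklevel=2,
            )
        for sid, assay, value in zip(meth["sample_id"], meth["assay"], rec):
            outcomes.setdefault(sid, {})[assay] = float(value)

    if "target" in wide and "reference" in wide:
        expr = wide.dropna(subset=["target", "reference"])
        if not expr.empty:
            if control_ids is None:
                raise ConfigurationError(
                    "control_ids required to quantify expression assays"
                )
            records = [
                ExpressionCtRecord(sid, assay, t, r)
                for sid, assay, t, r in zip(
                    expr["sample_id"], expr["assay"], expr["target"], expr["reference"]
                )
            ]
            rq = relative_expression(records, control_ids)
            for sid, gene, value in zip(rq["sample_id"], rq["gene"], rq["rq"]):
                outcomes.setdefault(sid, {})[gene] = float(value)

    result = pd.DataFrame.from_dict(outcomes, orient="index").sort_index()
    result.index.name = "sample_id"
    return result.reset_index()
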