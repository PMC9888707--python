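"""Hybrid audiogram / EHR phenotype derivation.

The study phenotype is *degree of hearing loss* (degree HL), an ordinal
severity scale from 0 (none) to 4 (profound) derived from the worse-ear
air-conduction pure-tone average (PTA).  Individuals with an audiogram are
assigned degree HL from their PTA; individuals without one are kept only if
they are phecode-defined controls (zero billing instances of the hearing-loss
phecode), in which case they are assigned degree 0.  Phecode cases and
single-instance (NA) individuals without audiometry are excluded, because
EHR-only labels are too noisy to grade severity.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

#: Frequencies (Hz) entering the pure-tone average.
PTA_FREQUENCIES = (500.0, 1000.0, 2000.0)

#: Upper PTA bound (dB HL) of degrees 0..3; above the last bound is degree 4.
DEGREE_UPPER_BOUNDS = (15.0, 25.0, 40.0, 55.0)

#: Worse-ear PTA above this value counts as audiogram-defined hearing loss.
AUDIOGRAM_POSITIVE_PTA = 25.0


class MissingDataError(ValueError):
    """Raised when an audiogram lacks the thresholds needed for a PTA."""


def compute_pta(thresholds: Mapping[float, float] | Iterable[float]) -> float:
    """Pure-tone average: arithmetic mean of thresholds at 500/1000/2000 Hz.

    Parameters
    ----------
    thresholds
        Either a mapping ``frequency_hz -> threshold_db`` (extra frequencies
        ignored) or an iterable of exactly three thresholds, taken to be the
        500/1000/2000 Hz values.

    Raises
    ------
    MissingDataError
        If any of the three PTA frequencies is absent.
    """
    if isinstance(thresholds, Mapping):
        try:
            vals = [float(thresholds[f]) for f in PTA_FREQUENCIES]
        except KeyError as exc:
            raise MissingDataError(f"missing threshold at {exc.args[0]} Hz") from exc
    else:
        vals = [float(v) for v in thresholds]
        if len(vals) != len(PTA_FREQUENCIES):
            raise MissingDataError(
                f"expected {len(PTA_FREQUENCIES)} thresholds, got {len(vals)}"
            )
    if any(math.isnan(v) for v in vals):
        raise MissingDataError("NaN threshold in pure-tone average input")
    return float(np.mean(vals))


def pta_to_degree(pta):
    """Map a PTA (dB HL) to degree HL 0-4.

    Bins follow the standard audiological categorisation: PTA <= 15 -> 0,
    (15, 25] -> 1 (mild), (25, 40] -> 2 (moderate), (40, 55] -> 3 (severe),
    > 55 -> 4 (profound).  Boundaries are half-open with the boundary value
    belonging to the lower degree, so fractional PTAs are always classified.

    Accepts a scalar or array; non-finite input raises ``ValueError``.
    """
    arr = np.asarray(pta, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("PTA must be finite")
    degree = np.searchsorted(np.asarray(DEGREE_UPPER_BOUNDS), arr, side="left")
    if np.isscalar(pta) or arr.ndim == 0:
        return int(degree)
    return degree.astype(int)


def phecode_status(count: int) -> str:
    """Case/control status from the number of phecode billing instances.

    Two or more instances -> ``"case"``; zero -> ``"control"``; exactly one
    -> ``"NA"`` (ambiguous, treated as missing).
    """
    count = int(count)
    if count < 0:
        raise ValueError("phecode instance count must be nonnegative")
    if count >= 2:
        return "case"
    if count == 0:
        return "control"
    return "NA"


def phecode_status_table(
    phecodes: pd.DataFrame,
    individuals: Iterable[str],
    phecode: str | None = None,
) -> pd.DataFrame:
    """Tabulate phecode instance counts and case/control status per individual.

    ``phecodes`` has one row per billing instance with columns
    ``individual_id`` and ``phecode``.  Individuals from ``individuals`` with
    no rows count zero instances (controls).  If ``phecode`` is given, only
    instances of that code are counted.
    """
    df = phecodes
    if phecode is not None and len(df):
        df = df[df["phecode"].astype(str) == str(phecode)]
    counts = df.groupby("individual_id").size() if len(df) else pd.Series(dtype=int)
    ids = pd.Index(individuals, name="individual_id")
    n = counts.reindex(ids, fill_value=0).astype(int)
    status = np.where(n >= 2, "case", np.where(n == 0, "control", "NA"))
    return pd.DataFrame({"individual_id": ids, "n_instances": n.values, "status": status})


def _ear_ptas(records: pd.DataFrame) -> pd.Series:
    """PTA per ear for air-conduction rows of a single exam; incomplete ears dropped."""
    air = records[records["conduction"] == "air"]
    air = air[air["frequency_hz"].isin(PTA_FREQUENCIES)]
    out = {}
    for ear, grp in air.groupby("ear"):
        freq_means = grp.groupby("frequency_hz")["threshold_db"].mean()
        if set(PTA_FREQUENCIES) <= set(freq_means.index):
            out[ear] = float(freq_means.loc[list(PTA_FREQUENCIES)].mean())
    return pd.Series(out, dtype=float)


def worse_ear_pta(records: pd.DataFrame, exam: str = "latest") -> float:
    """Worse-ear (larger) air-conduction PTA for one individual.

    ``records`` holds all audiogram rows for one individual with columns
    ``date, ear, conduction, frequency_hz, threshold_db``.  With multiple
    exams, ``exam="latest"`` (default) keeps the most recent exam date, and
    ``exam="worst"`` takes the maximum PTA over all exams.  If only one ear
    has a complete PTA it is returned.
    """
    if exam not in ("latest", "worst"):
        raise ValueError("exam must be 'latest' or 'worst'")
    if not len(records):
        raise MissingDataError("no audiogram records")
    if exam == "latest":
        latest = records["date"].max()
        ptas = _ear_ptas(records[records["date"] == latest])
        if not len(ptas):
            raise MissingDataError("no complete air-conduction ear at latest exam")
        return float(ptas.max())
    best = -np.inf
    for _, grp in records.groupby("date"):
        ptas = _ear_ptas(grp)
        if len(ptas):
            best = max(best, float(ptas.max()))
    if not np.isfinite(best):
        raise MissingDataError("no complete air-conduction ear in any exam")
    return best


def audiogram_pta_table(audiograms: pd.DataFrame, exam: str = "latest") -> pd.DataFrame:
    """Worse-ear air PTA and degree HL per individual with a usable audiogram.

    Individuals without a complete air-conduction ear at any exam are
    silently omitted (they contribute no audiometric phenotype).
    """
    rows = []
    for ind, grp in audiograms.groupby("individual_id"):
        try:
            pta = worse_ear_pta(grp, exam=exam)
        except MissingDataError:
            continue
        rows.append((ind, pta))
    if not rows:
        return pd.DataFrame(columns=["individual_id", "pta", "degree_hl"])
    out = pd.DataFrame(rows, columns=["individual_id", "pta"])
    out["degree_hl"] = pta_to_degree(out["pta"].to_numpy())
    return out


def assign_phenotype(
    audiograms: pd.DataFrame,
    phecodes: pd.DataFrame,
    individuals: Iterable[str],
    phecode: str | None = None,
    exam: str = "latest",
) -> pd.DataFrame:
    """Hybrid degree-HL assignment.

    Audiogram holders are graded from their worse-ear air PTA regardless of
    phecode status.  Everyone else is kept as degree 0 only if they are a
    phecode control; phecode cases and NA without audiometry are excluded
    with a recorded reason.

    Returns a table with one row per individual: ``individual_id, degree_hl,
    pta, source, included, exclusion_reason``.
    """
    ids = pd.Index(individuals, name="individual_id")
    if ids.has_duplicates:
        raise ValueError("duplicate individual ids")
    aud = audiogram_pta_table(audiograms, exam=exam).set_index("individual_id")
    phe = phecode_status_table(phecodes, ids, phecode=phecode).set_index("individual_id")

    out = pd.DataFrame(index=ids)
    out["degree_hl"] = np.nan
    out["pta"] = np.nan
    out["source"] = ""
    out["included"] = False
    out["exclusion_reason"] = ""

    has_aud = ids.intersection(aud.index)
    out.loc[has_aud, "degree_hl"] = aud.loc[has_aud, "degree_hl"].astype(float)
    out.loc[has_aud, "pta"] = aud.loc[has_aud, "pta"]
    out.loc[has_aud, "source"] = "audiogram"
    out.loc[has_aud, "included"] = True

    no_aud = ids.difference(has_aud)
    status = phe.loc[no_aud, "status"]
    ctrl = status.index[status == "control"]
    out.loc[ctrl, "degree_hl"] = 0.0
    out.loc[ctrl, "source"] = "phecode-control"
    out.loc[ctrl, "included"] = True
    case = status.index[status == "case"]
    out.loc[case, "exclusion_reason"] = "phecode-case-without-audiogram"
    na = status.index[status == "NA"]
    out.loc[na, "exclusion_reason"] = "phecode-NA-without-audiogram"

    out = out.reset_index()
    out["degree_hl"] = out["degree_hl"].astype("Float64")
    return out


def binarize_case_control(phenotypes: pd.DataFrame) -> pd.Series:
    """Binary labels: case iff degree HL in {2,3,4}, control iff in {0,1}.

    Excluded individuals get ``NA``.  Returns a nullable-boolean Series
    (True = case) indexed by individual id.
    """
    deg = phenotypes.set_index("individual_id")["degree_hl"]
    included = phenotypes.set_index("individual_id")["included"]
    lab = pd.Series(pd.NA, index=deg.index, dtype="boolean")
    lab[included & (deg >= 2)] = True
    lab[included & (deg <= 1)] = False
    return lab


def misclassification_table(
    phenotypes: pd.DataFrame,
    phecode_status_df: pd.DataFrame,
    positive_pta: float = AUDIOGRAM_POSITIVE_PTA,
) -> pd.DataFrame:
    """Cross-tabulate phecode status against audiogram positivity (PTA > 25 dB).

    Restricted to individuals with an audiometric PTA.  Returns one row per
    phecode status with counts and the fraction audiogram-positive; this is
    the case/control misclassification check that motivates the hybrid
    phenotype.
    """
    aud = phenotypes[phenotypes["source"] == "audiogram"][["individual_id", "pta"]]
    merged = aud.merge(phecode_status_df[["individual_id", "status"]], on="individual_id")
    merged["audiogram_positive"] = merged["pta"] > positive_pta
    rows = []
    for status, grp in merged.groupby("status"):
        rows.append(
            {
                "status": status,
                "n": len(grp),
                "n_audiogram_positive": int(grp["audiogram_positive"].sum()),
                "frac_audiogram_positive": float(grp["audiogram_positive"].mean()),
            }
        )
    return pd.DataFrame(rows)
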