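"""Patient-cohort LSF statistics.

Operates on a 40-patient table of per-method lung shunt fractions: planar
(anterior-liver/posterior-lung, photopeak only), SPECT/CT reconstructed with
no corrections / AC only / AC+SC (each with the 2 cm inferior-lung exclusion;
no-corrections and AC+SC also without it), and post-therapy Y-90 PET/CT
(AC+SC, with and without exclusion) for the 20-patient subset that underwent
post-therapy imaging.

The packaged fixture ``data/table3_lsf.csv`` is a versioned transcription of
that table; a checksum guards against accidental edits.  The per-patient AC
entry of patient 23 (0.3, below its AC+SC value 0.7) is transcribed as
printed but is a suspected typographical inversion with the AC+SC column;
no statistic computed here depends on it.

The paired t statistic is computed from its definition (mean difference over
its standard error, df = n-1) rather than delegated, so it can be
cross-checked against an independent permutation test.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

TABLE3_SHA256 = "a052f990dacf1de8fd891535284259ab1ea93ecbf78d87e157128c84af8acd97"

#: method tag -> fixture column
METHOD_COLUMNS = {
    "planar": "planar",
    "spect_noc": "spect_noc",
    "spect_ac": "spect_ac",
    "spect_acsc": "spect_acsc",
    "spect_noc_noexcl": "spect_noc_noexcl",
    "spect_acsc_noexcl": "spect_acsc_noexcl",
    "pet": "pet",
    "pet_noexcl": "pet_noexcl",
}


@dataclass(frozen=True)
class CohortSummary:
    method: str
    n: int
    mean: float
    min: float
    max: float

    def __post_init__(self):
        if not self.min <= self.mean <= self.max:
            raise ValueError("summary violates min <= mean <= max")

    def rounded(self, ndigits: int = 1) -> tuple[float, float, float]:
        """(mean, min, max) at the 1-decimal reporting convention."""
        return (round(self.mean, ndigits), round(self.min, ndigits), round(self.max, ndigits))

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_table3(path=None, verify_checksum: bool = True) -> pd.DataFrame:
    """Load the patient LSF table (packaged fixture by default)."""
    if path is None:
        ref = resources.files("lungshunt") / "data" / "table3_lsf.csv"
        raw = ref.read_bytes()
        if verify_checksum and hashlib.sha256(raw).hexdigest() != TABLE3_SHA256:
            raise ValueError("packaged LSF table failed its checksum — fixture was modified")
        from io import BytesIO

        df = pd.read_csv(BytesIO(raw))
    else:
        df = pd.read_csv(path)
    for col in METHOD_COLUMNS.values():
        if col not in df.columns:
            raise ValueError(f"missing column {col!r} in LSF table")
        vals = df[col].dropna()
        if ((vals < 0) | (vals > 100)).any():
            raise ValueError(f"column {col!r} holds LSF values outside [0, 100]")
    if df["pet"].notna().sum() != 20 and path is None:
        raise ValueError("packaged fixture must carry exactly 20 PET records")
    return df


def _column(records: pd.DataFrame, method: str) -> pd.Series:
    try:
        return records[METHOD_COLUMNS[method]]
    except KeyError:
        raise ValueError(f"unknown method {method!r}") from None


def _subset(records: pd.DataFrame, subset: str) -> pd.DataFrame:
    if subset == "all":
        return records
    if subset == "pet_only":
        return records[records["pet"].notna()]
    raise ValueError(f"unknown subset {subset!r}")


def summarize(records: pd.DataFrame, method: str, subset: str = "all") -> CohortSummary:
    """Arithmetic mean and range of one method's LSFs over a patient subset."""
    vals = _column(_subset(records, subset), method).dropna().to_numpy(float)
    if vals.size == 0:
        raise ValueError("empty subset")
    return CohortSummary(
        method=method, n=int(vals.size),
        mean=float(vals.mean()), min=float(vals.min()), max=float(vals.max()),
    )


def _paired(records, method_a, method_b, subset):
    sub = _subset(records, subset)
    a = _column(sub, method_a).to_numpy(float)
    b = _column(sub, method_b).to_numpy(float)
    ok = ~(np.isnan(a) | np.isnan(b))
    if not ok.all():
        raise ValueError("paired values missing for part of the subset")
    return a, b


def paired_t(records: pd.DataFrame, method_a: str, method_b: str, subset: str = "all"):
    """Two-sided paired t test, computed from the definition.

    t = mean(d) / (sd(d)/sqrt(n)) with d = a - b and df = n - 1.  Identical
    columns give t = 0, p = 1.
    """
    a, b = _paired(records, method_a, method_b, subset)
    n = a.size
    if n < 2:
        raise ValueError("paired t test needs n >= 2")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0:
        return 0.0, 1.0
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return float(t), float(p)


def pearson_r2(records: pd.DataFrame, method_a: str, method_b: str, subset: str = "all") -> float:
    """Squared Pearson correlation between two methods' LSFs."""
    a, b = _paired(records, method_a, method_b, subset)
    if a.size < 3:
        raise ValueError("correlation needs n >= 3")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero variance in one of the columns")
    r = np.corrcoef(a, b)[0, 1]
    return float(r**2)


def ratio_mean(records: pd.DataFrame, numerator_method: str, denominator_method: str,
               subset: str = "all") -> float:
    """Mean of per-patient LSF ratios (not the ratio of means, reported separately)."""
    sub = _subset(records, subset)
    a, b = _paired(records, numerator_method, denominator_method, subset)
    zero = np.flatnonzero(b == 0)
    if zero.size:
        pid = sub["patient"].iloc[zero[0]]
        raise ValueError(f"zero denominator LSF for patient {pid}")
    return float((a / b).mean())


def ratio_of_means(records: pd.DataFrame, numerator_method: str, denominator_method: str,
                   subset: str = "all") -> float:
    a, b = _paired(records, numerator_method, denominator_method, subset)
    if b.mean() == 0:
        raise ValueError("zero denominator mean")
    return float(a.mean() / b.mean())


def diff_stats(records: pd.DataFrame, method_a: str, method_b: str, subset: str = "all",
               threshold_points: float = 5.0):
    """Max |a-b| over the subset and the count of patients exceeding threshold."""
    a, b = _paired(records, method_a, method_b, subset)
    if a.size == 0:
        raise ValueError("empty subset")
    d = np.abs(a - b)
    return float(d.max()), int((d > threshold_points).sum())


def cohort_report(records: pd.DataFrame | None = None) -> dict:
    """All headline cohort statistics in one serializable dictionary."""
    if records is None:
        records = load_table3()
    rep: dict = {}
    for method in ("planar", "spect_acsc"):
        s = summarize(records, method, "all")
        rep[f"{method}_all"] = s.as_dict()
    for method in ("planar", "spect_acsc", "pet"):
        s = summarize(records, method, "pet_only")
        rep[f"{method}_pet_subset"] = s.as_dict()
    for pair in (("planar", "pet"), ("spect_acsc", "pet")):
        mx, n5 = diff_stats(records, *pair, "pet_only", 5.0)
        t, p = paired_t(records, *pair, "pet_only")
        rep[f"{pair[0]}_vs_{pair[1]}"] = {
            "max_abs_diff": mx, "n_exceeding_5_points": n5, "t": t, "p": p,
        }
    rep["planar_to_spect_acsc_mean_ratio"] = ratio_mean(records, "planar", "spect_acsc")
    rep["planar_to_spect_acsc_ratio_of_means"] = ratio_of_means(records, "planar", "spect_acsc")
    rep["planar_vs_spect_acsc_r2"] = pearson_r2(records, "planar", "spect_acsc")
    return rep
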