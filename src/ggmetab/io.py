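"""Reading and writing concentration tables plus distribution diagnostics."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import norm

from .kinetics import ConcentrationEnsemble

__all__ = [
    "read_concentration_table",
    "write_concentration_table",
    "lognormality_check",
]


def read_concentration_table(
    path, logged: bool = True, sep: str | None = None, classes: dict[str, str] | None = None
) -> ConcentrationEnsemble:
    """Read a samples x metabolites table into a log-scale ensemble.

    With ``logged=False`` the values are raw concentrations and the natural
    log is applied; non-positive raw values are rejected with their location.
    Missing values are rejected (no imputation).  The delimiter is sniffed
    from the header when ``sep`` is None.
    """
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    if df.columns.duplicated().any():
        raise ValueError("duplicate metabolite ids in header")
    if df.isna().any().any():
        rows, cols = np.where(df.isna())
        raise ValueError(
            f"missing value at row {rows[0]}, column {df.columns[cols[0]]!r}; "
            "imputation is not supported"
        )
    body = df.apply(pd.to_numeric)
    if not logged:
        if (body <= 0).any().any():
            rows, cols = np.where(body.to_numpy() <= 0)
            raise ValueError(
                f"non-positive raw concentration at row {rows[0]}, "
                f"column {df.columns[cols[0]]!r}"
            )
        body = np.log(body)
    return ConcentrationEnsemble(data=body, classes=classes)


def write_concentration_table(ensemble: ConcentrationEnsemble, path, sep: str = "\t") -> None:
    """Write the log-scale ensemble as delimited text with a metabolite header."""
    ensemble.data.to_csv(path, sep=sep, index=False)


def lognormality_check(X_raw: pd.DataFrame) -> pd.DataFrame:
    """Compare normality of raw vs log-transformed values per metabolite.

    The straightness of a normal QQ-plot is summarized as the correlation
    between ordered sample values and normal plotting-position quantiles;
    whichever transform is closer to 1 is preferred.  Constant columns are
    flagged as undefined.
    """
    if X_raw.shape[0] < 10:
        raise ValueError("need at least 10 samples for the QQ diagnostic")
    if (X_raw <= 0).any().any():
        raise ValueError("raw concentrations must be strictly positive")
    n = X_raw.shape[0]
    # Blom-style plotting positions
    quantiles = norm.ppf((np.arange(1, n + 1) - 0.375) / (n + 0.25))
    rows = []
    for col in X_raw.columns:
        vals = X_raw[col].to_numpy(dtype=float)
        if np.all(vals == vals[0]):
            rows.append({"metabolite": col, "r_raw": np.nan, "r_log": np.nan,
                         "preferred": "undefined"})
            continue
        r_raw = float(np.corrcoef(np.sort(vals), quantiles)[0, 1])
        r_log = float(np.corrcoef(np.sort(np.log(vals)), quantiles)[0, 1])
        rows.append(
            {
                "metabolite": col,
                "r_raw": r_raw,
                "r_log": r_log,
                "preferred": "log" if r_log >= r_raw else "raw",
            }
        )
    return pd.DataFrame(rows)
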