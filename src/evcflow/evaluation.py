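"""Error evaluation of effective values against reference concentrations.

Each model result is matched to a reference reading (typically gas
chromatography) by ``(sample_id, gas)``.  The report carries per-row
absolute and relative errors, flags rows beyond the allowable relative
error, and summarizes per gas and pooled: the maximum relative error, the
fraction of rows below 1 %, and a histogram of relative errors in 0.5 %
closed-open bins.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .effective_value import STATUS_OK, EffectiveValue
from .stream_io import GASES, ReferenceTable

__all__ = ["ErrorReport", "evaluate", "ALLOWABLE_REL_ERROR_PCT", "HIST_BIN_PCT"]

ALLOWABLE_REL_ERROR_PCT = 2.5
HIST_BIN_PCT = 0.5


@dataclass(frozen=True)
class ErrorReport:
    """Row-level errors plus per-gas and pooled summaries.

    ``rows`` has columns sample_id, gas, evc_value, gc_value, abs_error,
    rel_error_pct, within_allowable.  ``summaries`` maps gas label (and
    ``"pooled"``) to a dict with max_rel_error_pct, fraction_below_1pct_pct,
    n, and ``histogram`` as (bin_lower_pct, count) pairs.  ``flagged`` lists
    results excluded from the summary because their status was not ok;
    ``unmatched_results`` / ``unmatched_references`` record keys present on
    only one side.
    """

    rows: pd.DataFrame
    summaries: dict
    flagged: pd.DataFrame
    unmatched_results: tuple
    unmatched_references: tuple

    def summary_text(self) -> str:
        lines = []
        for gas, s in self.summaries.items():
            lines.append(
                f"{gas}: n={s['n']}, max relative error "
                f"{s['max_rel_error_pct']:.2f}%, "
                f"{s['fraction_below_1pct_pct']:.1f}% of rows below 1%"
            )
        if len(self.flagged):
            lines.append(f"{len(self.flagged)} result(s) excluded (status not ok)")
        if self.unmatched_results:
            lines.append(f"unmatched results: {list(self.unmatched_results)}")
        if self.unmatched_references:
            lines.append(f"unmatched references: {list(self.unmatched_references)}")
        return "\n".join(lines)


def _histogram(rel_pct: np.ndarray) -> list:
    """Counts of relative errors in closed-open 0.5 % bins, up to the max row."""
    if len(rel_pct) == 0:
        return []
    n_bins = int(np.floor(rel_pct.max() / HIST_BIN_PCT)) + 1
    idx = np.floor(rel_pct / HIST_BIN_PCT).astype(int)
    counts = np.bincount(idx, minlength=n_bins)
    return [(round(b * HIST_BIN_PCT, 10), int(c)) for b, c in enumerate(counts)]


def _summarize(df: pd.DataFrame) -> dict:
    rel = df["rel_error_pct"].to_numpy()
    return {
        "n": int(len(df)),
        "max_rel_error_pct": float(rel.max()) if len(rel) else float("nan"),
        "fraction_below_1pct_pct": (
            float(100.0 * np.mean(rel < 1.0)) if len(rel) else float("nan")
        ),
        "histogram": _histogram(rel),
    }


def evaluate(
    results: Sequence,
    references: ReferenceTable,
    sample_ids: Optional[Sequence] = None,
    allowable_pct: float = ALLOWABLE_REL_ERROR_PCT,
) -> ErrorReport:
    """Match results to references and compute the error statistics.

    Parameters
    ----------
    results:
        :class:`EffectiveValue` sequence, or any records with fields
        ``sample_id, gas, value, status`` (dicts or objects).
    references:
        Reference table with one ``gc_value`` per (sample_id, gas).
    sample_ids:
        When ``results`` are :class:`EffectiveValue` (which carry no sample
        identity), one id per *window*, in window order; both gas results of
        a window share the id.  Ignored when results already carry
        ``sample_id``.
    allowable_pct:
        Relative-error bound used for the ``within_allowable`` flag.

    Raises
    ------
    ValueError
        If no ok-status result matches any reference.
    """
    recs = _coerce_results(results, sample_ids)
    ref_df = references.to_frame()

    merged = recs.merge(ref_df, on=["sample_id", "gas"], how="outer", indicator=True)
    unmatched_res = tuple(
        map(
            tuple,
            merged.loc[merged["_merge"] == "left_only", ["sample_id", "gas"]]
            .itertuples(index=False),
        )
    )
    unmatched_ref = tuple(
        map(
            tuple,
            merged.loc[merged["_merge"] == "right_only", ["sample_id", "gas"]]
            .itertuples(index=False),
        )
    )
    both = merged[merged["_merge"] == "both"].drop(columns="_merge").copy()

    flagged = both[both["status"] != STATUS_OK].reset_index(drop=True)
    ok = both[both["status"] == STATUS_OK].copy()
    if len(ok) == 0:
        raise ValueError("no ok-status result matches any reference entry")

    ok["evc_value"] = ok.pop("value").astype(float)
    ok["abs_error"] = (ok["evc_value"] - ok["gc_value"]).abs()
    ok["rel_error_pct"] = 100.0 * ok["abs_error"] / ok["gc_value"]
    ok["within_allowable"] = ok["rel_error_pct"] <= allowable_pct
    rows = ok[
        [
            "sample_id",
            "gas",
            "evc_value",
            "gc_value",
            "abs_error",
            "rel_error_pct",
            "within_allowable",
        ]
    ].reset_index(drop=True)

    summaries = {}
    for gas in GASES:
        sub = rows[rows["gas"] == gas]
        if len(sub):
            summaries[gas] = _summarize(sub)
    summaries["pooled"] = _summarize(rows)

    return ErrorReport(
        rows=rows,
        summaries=summaries,
        flagged=flagged.reset_index(drop=True),
        unmatched_results=unmatched_res,
        unmatched_references=unmatched_ref,
    )


def _coerce_results(results: Sequence, sample_ids: Optional[Sequence]) -> pd.DataFrame:
    rows = []
    if results and isinstance(results[0], EffectiveValue):
        if sample_ids is None:
            # one id per distinct window, in order of appearance
            order: dict = {}
            for r in results:
                order.setdefault(r.window_ref, len(order))
            ids = {ref: i for ref, i in order.items()}
            rows = [
                {
                    "sample_id": ids[r.window_ref],
                    "gas": r.gas,
                    "value": r.value,
                    "status": r.status,
                }
                for r in results
            ]
        else:
            window_refs = list(dict.fromkeys(r.window_ref for r in results))
            if len(sample_ids) != len(window_refs):
                raise ValueError(
                    f"{len(sample_ids)} sample ids for {len(window_refs)} windows"
                )
            ids = dict(zip(window_refs, sample_ids))
            rows = [
                {
                    "sample_id": ids[r.window_ref],
                    "gas": r.gas,
                    "value": r.value,
                    "status": r.status,
                }
                for r in results
            ]
    else:
        for r in results:
            if isinstance(r, dict):
                get = lambda k, d=None, _r=r: _r.get(k, d)
            else:
                get = lambda k, d=None, _r=r: getattr(_r, k, d)
            rows.append(
                {
                    "sample_id": get("sample_id"),
                    "gas": get("gas"),
                    "value": get("value"),
                    "status": get("status", STATUS_OK),
                }
            )
    return pd.DataFrame(rows, columns=["sample_id", "gas", "value", "status"])
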