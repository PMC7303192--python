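"""Cohort outcome tables and their summary statistics.

The package ships the per-patient outcome fixtures of the two device
cohorts — 14 balloon-expandable (SapienXT) and 14 self-expandable
(CoreValve) cases — with the measured fluoroscopic stent diameters, the
simulation-vs-fluoroscopy diameter differences, the echocardiographic
paravalvular-leak descriptors, and (for the self-expandable cohort) the
three regional maximum-principal-strain statistics.  This module recomputes
cohort summaries from those per-patient values and summarises batches of
synthetic deployment results in the same schema.

Standard-deviation convention: both the population (ddof=0) and sample
(ddof=1) values are computed and reported; ``summarize`` records which one
matches a given printed value when asked.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from io import StringIO

import numpy as np
import pandas as pd

__all__ = [
    "load_sapienxt_table",
    "load_corevalve_table",
    "load_strain_table",
    "summarize",
    "pooled_mean",
    "extremum_case",
    "agreement_stats",
    "parse_pvl",
    "CohortSummary",
]


def _read(name: str) -> pd.DataFrame:
    text = resources.files("tavisim.data").joinpath(name).read_text()
    return pd.read_csv(StringIO(text), sep="\t")


def load_sapienxt_table() -> pd.DataFrame:
    """Per-patient outcomes of the balloon-expandable cohort."""
    return _read("table1_sapienxt.tsv")


def load_corevalve_table() -> pd.DataFrame:
    """Per-patient outcomes of the self-expandable cohort."""
    return _read("table2_corevalve.tsv")


def load_strain_table() -> pd.DataFrame:
    """Regional maximum-principal-strain statistics, self-expandable cohort."""
    return _read("table4_strains.tsv")


@dataclass(frozen=True)
class CohortSummary:
    """Mean and standard deviation of one column of a cohort table."""

    column: str
    n: int
    mean: float
    std_population: float
    std_sample: float
    max_case: tuple  # (patient ids, value)

    def std(self, convention: str = "sample") -> float:
        return self.std_sample if convention == "sample" else self.std_population


def summarize(records: pd.DataFrame, column: str) -> CohortSummary:
    """Arithmetic mean and both-convention standard deviations of a column,
    over non-missing entries only."""
    vals = pd.to_numeric(records[column], errors="coerce").dropna()
    if vals.empty:
        raise ValueError(f"column {column!r} has no numeric entries")
    ids, value = extremum_case(records, column)
    return CohortSummary(
        column=column,
        n=int(vals.size),
        mean=float(vals.mean()),
        std_population=float(vals.std(ddof=0)),
        std_sample=float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
        max_case=(ids, value),
    )


def pooled_mean(records_a: pd.DataFrame, records_b: pd.DataFrame, column: str) -> float:
    """Mean of a column over the union of two cohorts."""
    vals = pd.concat(
        [
            pd.to_numeric(records_a.get(column), errors="coerce"),
            pd.to_numeric(records_b.get(column), errors="coerce"),
        ]
    ).dropna()
    if vals.empty:
        raise ValueError(f"column {column!r} empty in both cohorts")
    return float(vals.mean())


def extremum_case(records: pd.DataFrame, column: str):
    """Patient id(s) and value of the column maximum (ties return all ids)."""
    vals = pd.to_numeric(records[column], errors="coerce")
    vmax = vals.max()
    ids = records.loc[vals == vmax, "patient_id"].tolist()
    return ids, float(vmax)


def agreement_stats(predicted, observed) -> dict:
    """2x2 agreement of boolean predictions vs observations."""
    p = np.asarray(predicted, dtype=bool)
    o = np.asarray(observed, dtype=bool)
    if p.shape != o.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {o.shape}")
    tp = int(np.sum(p & o))
    tn = int(np.sum(~p & ~o))
    fp = int(np.sum(p & ~o))
    fn = int(np.sum(~p & o))
    n = p.size
    return {
        "fraction_correct": (tp + tn) / n if n else float("nan"),
        "sensitivity": tp / (tp + fn) if (tp + fn) else float("nan"),
        "specificity": tn / (tn + fp) if (tn + fp) else float("nan"),
        "tp": tp,
        "tn": tn,
        "fp": fp,
        "fn": fn,
    }


_CUSP_RE = re.compile(r"\b(NCC|RCC|LCC)\b")


def parse_pvl(text: str) -> dict:
    """Map a free-text echo leak descriptor to {present, sinuses}.

    Descriptors starting with "No PVL" (with or without qualifiers) are
    absent; anything else is a present leak, located at every cusp token the
    text names (a jet "in RCC-NCC" touches both sinuses).  The mapping is a
    plain rule, editable by overriding this function or pre-processing the
    table.
    """
    t = str(text).strip()
    if t.lower().startswith("no pvl"):
        return {"present": False, "sinuses": set()}
    sinuses = set(_CUSP_RE.findall(t.upper().replace("-", " ")))
    return {"present": True, "sinuses": sinuses}


def summarize_batch(rows: list[dict]) -> pd.DataFrame:
    """Assemble synthetic per-case outcome records into the cohort schema.

    Each row is a dict with at minimum ``patient_id``, ``device_family``,
    ``size_mm`` and the computed outcome fields (projected diameter, PVL
    presence/sinuses, strain statistics where applicable).
    """
    return pd.DataFrame(rows)
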