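"""Differential HDX-MS analysis at the peptide level.

Input is a table of per-peptide deuterium uptake fractions over labeling
timepoints, measured with and without a binder.  The module computes
uptake differences (bound − apo) per peptide and timepoint, flags
peptides whose uptake drops below a threshold at enough timepoints
(candidate epitope), and — when a graft design is supplied — annotates
each flagged peptide by whether it covers grafted, scaffold, linker or
mixed positions of the chimera.

The defaults (Δ ≤ −0.05 at ≥ 2 timepoints) are deliberately simple,
tunable rules; raw differences are always reported next to the calls.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .graft_design import GraftDesign

__all__ = ["HDXPeptide", "load_uptake", "HDXDifferenceReport",
           "hdx_difference", "EpitopeCall", "call_epitope"]


@dataclass
class HDXPeptide:
    """Uptake curve of one peptic peptide under one condition."""

    start_res: int
    end_res: int
    sequence: str
    condition: str                  # 'apo' or 'bound'
    timepoints_s: np.ndarray
    uptake: np.ndarray              # deuteration fraction in [0, 1]
    replicates: np.ndarray | None = None   # optional (n_rep, n_t)

    def __post_init__(self):
        self.timepoints_s = np.asarray(self.timepoints_s, dtype=float)
        self.uptake = np.asarray(self.uptake, dtype=float)
        if self.timepoints_s.shape != self.uptake.shape:
            raise ValueError("timepoints and uptake must align")
        if np.any((self.uptake < 0) | (self.uptake > 1)):
            raise ValueError(
                f"peptide {self.start_res}-{self.end_res} "
                f"({self.condition}): uptake outside [0, 1]")
        n_pro = self.sequence[1:].count("P") if self.sequence else 0
        if self.sequence and len(self.sequence) - n_pro - 1 < 1:
            raise ValueError(
                f"peptide {self.start_res}-{self.end_res}: no exchangeable "
                "amides")

    @property
    def key(self) -> tuple[int, int, str]:
        return (self.start_res, self.end_res, self.sequence)


_REQUIRED_COLS = {"start_res", "end_res", "sequence", "condition",
                  "timepoint_s"}


def load_uptake(source: str | os.PathLike | pd.DataFrame) -> list[HDXPeptide]:
    """Read an uptake CSV into validated peptide records.

    Expected columns: ``start_res, end_res, sequence, condition,
    timepoint_s`` and either ``uptake`` (fraction) or the mass triplet
    ``mass_t, mass_zero, mass_full`` from which the back-exchange
    normalized ratio (m_t − m_0)/(m_full − m_0) is computed.  An optional
    ``replicate`` column averages into the curve and is kept for
    statistics.
    """
    df = source if isinstance(source, pd.DataFrame) else pd.read_csv(source)
    missing = _REQUIRED_COLS - set(df.columns)
    if missing:
        raise ValueError(f"uptake table lacks columns: {sorted(missing)}")
    if "uptake" not in df.columns:
        for c in ("mass_t", "mass_zero", "mass_full"):
            if c not in df.columns:
                raise ValueError(
                    "uptake table needs either an 'uptake' column or "
                    "mass_t/mass_zero/mass_full")
        denom = df["mass_full"] - df["mass_zero"]
        if np.any(denom <= 0):
            raise ValueError("mass_full must exceed mass_zero")
        df = df.assign(uptake=(df["mass_t"] - df["mass_zero"]) / denom)
    if np.any((df["uptake"] < -1e-9) | (df["uptake"] > 1 + 1e-9)):
        bad = df[(df["uptake"] < 0) | (df["uptake"] > 1)]
        raise ValueError(
            f"{len(bad)} uptake values outside [0, 1] after normalization")
    df = df.assign(uptake=df["uptake"].clip(0.0, 1.0))

    peptides = []
    for (s, e, seq, cond), g in df.groupby(
            ["start_res", "end_res", "sequence", "condition"], sort=True):
        reps = None
        if "replicate" in g.columns and g["replicate"].nunique() > 1:
            wide = g.pivot_table(index="replicate", columns="timepoint_s",
                                 values="uptake")
            reps = wide.to_numpy()
            t = wide.columns.to_numpy(dtype=float)
            u = wide.mean(axis=0).to_numpy()
        else:
            g = g.sort_values("timepoint_s")
            t = g["timepoint_s"].to_numpy(dtype=float)
            u = g["uptake"].to_numpy(dtype=float)
        peptides.append(HDXPeptide(int(s), int(e), str(seq), str(cond),
                                   t, u, reps))
    return peptides


@dataclass
class PeptideDifference:
    start_res: int
    end_res: int
    sequence: str
    timepoints_s: np.ndarray
    delta: np.ndarray               # bound - apo per timepoint
    summary: float                  # mean over timepoints
    p_value: float | None = None
    q_value: float | None = None


@dataclass
class HDXDifferenceReport:
    differences: list[PeptideDifference]
    unmatched_apo: list[tuple[int, int, str]] = field(default_factory=list)
    unmatched_bound: list[tuple[int, int, str]] = field(default_factory=list)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for d in self.differences:
            for t, x in zip(d.timepoints_s, d.delta):
                rows.append((d.start_res, d.end_res, d.sequence, t, x,
                             d.summary))
        return pd.DataFrame(rows, columns=["start_res", "end_res",
                                           "sequence", "timepoint_s",
                                           "delta", "summary"])


def hdx_difference(apo: list[HDXPeptide], bound: list[HDXPeptide],
                   welch_test: bool = False) -> HDXDifferenceReport:
    """Per-peptide uptake differences Δ(t) = bound(t) − apo(t).

    Peptides are matched on (start, end, sequence); unmatched records are
    reported separately.  With ``welch_test`` and replicate data on both
    sides, a Welch t-test per peptide (on time-averaged uptake) with
    Benjamini–Hochberg adjustment across peptides is added.
    """
    apo_by = {p.key: p for p in apo}
    bound_by = {p.key: p for p in bound}
    common = sorted(set(apo_by) & set(bound_by))
    if not common:
        raise ValueError("no matching peptides between conditions")

    diffs = []
    for key in common:
        a, b = apo_by[key], bound_by[key]
        order_a = np.argsort(a.timepoints_s)
        order_b = np.argsort(b.timepoints_s)
        if not np.allclose(a.timepoints_s[order_a], b.timepoints_s[order_b]):
            raise ValueError(
                f"peptide {key[0]}-{key[1]}: timepoints differ between "
                "conditions")
        delta = b.uptake[order_b] - a.uptake[order_a]
        p = None
        if welch_test and a.replicates is not None and b.replicates is not None:
            p = float(stats.ttest_ind(b.replicates.mean(axis=1),
                                      a.replicates.mean(axis=1),
                                      equal_var=False).pvalue)
        diffs.append(PeptideDifference(
            key[0], key[1], key[2], a.timepoints_s[order_a], delta,
            float(delta.mean()), p_value=p))

    if welch_test and any(d.p_value is not None for d in diffs):
        tested = [d for d in diffs if d.p_value is not None]
        pvals = np.array([d.p_value for d in tested])
        order = np.argsort(pvals)
        m = len(pvals)
        q = np.empty(m)
        prev = 1.0
        for rank_pos, idx in enumerate(order[::-1]):
            k = m - rank_pos
            prev = min(prev, pvals[idx] * m / k)
            q[idx] = prev
        for d, qv in zip(tested, q):
            d.q_value = float(qv)

    return HDXDifferenceReport(
        diffs,
        unmatched_apo=sorted(set(apo_by) - set(bound_by)),
        unmatched_bound=sorted(set(bound_by) - set(apo_by)),
    )


@dataclass
class EpitopeCall:
    start_res: int
    end_res: int
    sequence: str
    summary_delta: float
    n_protected_timepoints: int
    region: str | None = None       # grafted | scaffold | linker | mixed


def call_epitope(report: HDXDifferenceReport,
                 threshold: float = -0.05,
                 min_timepoints: int = 2,
                 design: GraftDesign | None = None) -> list[EpitopeCall]:
    """Flag protected peptides: Δ ≤ threshold at ≥ min_timepoints.

    With a design, each call is annotated by the source of the chimera
    positions it covers (peptide boundaries in construct numbering).
    """
    if not report.differences:
        raise ValueError("empty difference report")
    calls = []
    for d in report.differences:
        n_prot = int(np.sum(d.delta <= threshold))
        if n_prot < min_timepoints:
            continue
        region = None
        if design is not None:
            sources = {e.source for e in design.index_map
                       if d.start_res <= e.chimera_pos <= d.end_res}
            if len(sources) == 1:
                source = sources.pop()
                region = "grafted" if source == "donor" else source
            elif sources:
                region = "mixed"
        calls.append(EpitopeCall(d.start_res, d.end_res, d.sequence,
                                 d.summary, n_prot, region))
    return calls
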