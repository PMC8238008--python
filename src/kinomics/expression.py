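"""Differential-expression filtering, enrichment and qPCR statistics.

The DE rule calls a transcript up-regulated when log2FC > 1, p < 0.05 and
FDR < 0.05 (all strict), down-regulated symmetrically, and not significant
otherwise.  GO enrichment is an upper-tail hypergeometric test of each
term's foreground count against a supplied background annotation, with
Benjamini–Hochberg step-up correction; no ontology-graph propagation is
performed — terms are tested as given.

The qPCR relative-expression ratio follows the efficiency-corrected
(Pfaffl/REST) convention

    ratio = E_target ** dCt_target / geo-mean_r ( E_r ** dCt_r )

with dCt = mean control Ct - mean treated Ct, and significance from a
fixed-reallocation randomization test: control/treated labels are permuted
jointly across the target and reference genes (the replicate is the
permutation unit) and the two-sided, fold-symmetric extremeness of the
ratio relative to 1 is compared against the permutation distribution.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import hypergeom


# --------------------------------------------------------------------- DE

def de_filter(table: pd.DataFrame, lfc_threshold: float = 1.0,
              p_threshold: float = 0.05,
              fdr_threshold: float = 0.05) -> pd.DataFrame:
    """Add an up/down/ns ``call`` column; all thresholds strict."""
    for col in ("log2FC", "p", "fdr"):
        if col not in table.columns:
            raise ValueError(f"DE table missing column {col!r}")
    out = table.copy()
    sig = (out["p"] < p_threshold) & (out["fdr"] < fdr_threshold)
    out["call"] = "ns"
    out.loc[sig & (out["log2FC"] > lfc_threshold), "call"] = "up"
    out.loc[sig & (out["log2FC"] < -lfc_threshold), "call"] = "down"
    return out


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted values, in input order."""
    p = np.asarray(list(pvalues), dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return p
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def family_tally(catalog: pd.DataFrame, de_records: pd.DataFrame,
                 transcript_to_protein=None) -> pd.DataFrame:
    """Distinct up/down transcript counts per family per treatment.

    ``de_records`` needs columns transcript_id, treatment, call.
    Transcripts that map to no catalog family are tallied under the
    family ``"unmapped"``.  Ordering is deterministic: count descending,
    then family name.
    """
    fam_of = dict(zip(catalog["protein_id"], catalog["family"]))
    rows = []
    sub = de_records[de_records["call"].isin(["up", "down"])]
    for (treatment, call), grp in sub.groupby(["treatment", "call"]):
        counts: dict[str, set] = {}
        for tid in grp["transcript_id"]:
            pid = (transcript_to_protein(tid) if transcript_to_protein
                   else tid)
            fam = fam_of.get(pid, "unmapped")
            if pd.isna(fam):
                fam = "unmapped"
            counts.setdefault(fam, set()).add(tid)
        for fam, tids in counts.items():
            rows.append({"treatment": treatment, "call": call,
                         "family": fam, "n_transcripts": len(tids)})
    df = pd.DataFrame(rows, columns=["treatment", "call", "family",
                                     "n_transcripts"])
    return df.sort_values(
        ["treatment", "call", "n_transcripts", "family"],
        ascending=[True, True, False, True]).reset_index(drop=True)


def crosstalk(up_sets: dict[str, set[str]],
              families: dict[str, str] | None = None):
    """Transcripts up-regulated in every assay, plus pairwise overlaps."""
    if len(up_sets) < 2:
        raise ValueError("crosstalk needs at least two assays")
    assays = sorted(up_sets)
    shared = set.intersection(*(set(up_sets[a]) for a in assays))
    pairwise = {
        (a, b): set(up_sets[a]) & set(up_sets[b])
        for a, b in combinations(assays, 2)
    }
    shared_families = (sorted({families[t] for t in shared if t in families})
                       if families else [])
    return {"shared": shared, "pairwise": pairwise,
            "shared_families": shared_families}


# ------------------------------------------------------------------ GO

@dataclass
class EnrichmentResult:
    term: str
    name: str
    k: int
    n: int
    K: int
    N: int
    p: float
    fdr: float
    enriched: bool


def go_enrichment(foreground: set[str], background: set[str],
                  annotations: pd.DataFrame, p_cutoff: float = 0.05,
                  fdr_cutoff: float = 0.05) -> list[EnrichmentResult]:
    """Hypergeometric GO-term over-representation with BH correction.

    ``annotations`` needs columns gene, term (and optionally name).
    Terms with zero foreground genes are skipped.
    """
    foreground, background = set(foreground), set(background)
    missing = foreground - background
    if missing:
        raise ValueError(
            f"foreground genes absent from background: {sorted(missing)[:5]}")
    ann = annotations[annotations["gene"].isin(background)]
    names = {}
    if "name" in ann.columns:
        names = dict(zip(ann["term"], ann["name"]))
    N, n = len(background), len(foreground)
    raw = []
    for term, grp in ann.groupby("term"):
        genes = set(grp["gene"])
        k = len(genes & foreground)
        if k == 0:
            continue
        K = len(genes)
        p = float(hypergeom.sf(k - 1, N, K, n))
        raw.append((term, k, K, p))
    qvals = bh_fdr([r[3] for r in raw])
    out = [EnrichmentResult(term=t, name=names.get(t, ""), k=k, n=n, K=K,
                            N=N, p=p, fdr=q,
                            enriched=(p < p_cutoff and q < fdr_cutoff))
           for (t, k, K, p), q in zip(raw, qvals)]
    out.sort(key=lambda r: (r.p, r.term))
    return out


# ----------------------------------------------------------------- qPCR

@dataclass
class QpcrResult:
    target_id: str
    e_target: float
    e_refs: list[float]
    delta_ct_target: float
    delta_ct_refs: list[float]
    ratio: float
    p_random: float


def efficiency_from_percent(pct: float) -> float:
    """Convert a percent amplification efficiency (100% = doubling)
    into fold-per-cycle: E = 1 + pct/100."""
    return 1.0 + pct / 100.0


def _ratio_from_cts(ct_ctrl_t, ct_trt_t, ct_ctrl_refs, ct_trt_refs,
                    e_target, e_refs):
    d_t = float(np.mean(ct_ctrl_t) - np.mean(ct_trt_t))
    d_refs = [float(np.mean(c) - np.mean(t))
              for c, t in zip(ct_ctrl_refs, ct_trt_refs)]
    num = e_target ** d_t
    ref_terms = [e ** d for e, d in zip(e_refs, d_refs)]
    denom = float(np.prod(ref_terms)) ** (1.0 / len(ref_terms))
    return num / denom, d_t, d_refs


def rest_ratio(ct_control_target, ct_treated_target, ct_control_refs,
               ct_treated_refs, e_target: float = 2.0, e_refs=None,
               n_permutations: int = 2000, seed: int | None = None,
               target_id: str = "") -> QpcrResult:
    """Efficiency-corrected expression ratio with a randomization test.

    ``ct_control_refs``/``ct_treated_refs`` are lists of per-reference
    replicate arrays aligned with the target replicates.  Reallocations
    are exhaustive when the number of distinct control/treated label
    splits does not exceed ``n_permutations``, otherwise Monte Carlo.
    """
    ct_ctrl_t = np.asarray(ct_control_target, dtype=float)
    ct_trt_t = np.asarray(ct_treated_target, dtype=float)
    if len(ct_ctrl_t) < 2 or len(ct_trt_t) < 2:
        raise ValueError("need >= 2 replicates per group")
    ctrl_refs = [np.asarray(a, dtype=float) for a in ct_control_refs]
    trt_refs = [np.asarray(a, dtype=float) for a in ct_treated_refs]
    if e_refs is None:
        e_refs = [2.0] * len(ctrl_refs)
    if e_target <= 1 or any(e <= 1 for e in e_refs):
        raise ValueError("amplification efficiencies must exceed 1")

    ratio, d_t, d_refs = _ratio_from_cts(
        ct_ctrl_t, ct_trt_t, ctrl_refs, trt_refs, e_target, e_refs)

    # pooled samples; a reallocation picks which indices act as "control"
    pool_t = np.concatenate([ct_ctrl_t, ct_trt_t])
    pool_refs = [np.concatenate([c, t]) for c, t in zip(ctrl_refs, trt_refs)]
    n_ctrl, n_tot = len(ct_ctrl_t), len(pool_t)

    def realloc_ratio(ctrl_idx: np.ndarray) -> float:
        mask = np.zeros(n_tot, dtype=bool)
        mask[ctrl_idx] = True
        r, _, _ = _ratio_from_cts(
            pool_t[mask], pool_t[~mask],
            [p[mask] for p in pool_refs], [p[~mask] for p in pool_refs],
            e_target, e_refs)
        return r

    def extremeness(r: float) -> float:
        return max(r, 1.0 / r)

    obs = extremeness(ratio)
    from math import comb
    n_exhaustive = comb(n_tot, n_ctrl)
    count = total = 0
    if n_exhaustive <= n_permutations:
        for ctrl_idx in combinations(range(n_tot), n_ctrl):
            r = realloc_ratio(np.array(ctrl_idx))
            total += 1
            if extremeness(r) >= obs - 1e-12:
                count += 1
    else:
        rng = np.random.default_rng(seed)
        for _ in range(n_permutations):
            ctrl_idx = rng.choice(n_tot, size=n_ctrl, replace=False)
            r = realloc_ratio(ctrl_idx)
            total += 1
            if extremeness(r) >= obs - 1e-12:
                count += 1
    return QpcrResult(target_id=target_id, e_target=e_target,
                      e_refs=list(e_refs), delta_ct_target=d_t,
                      delta_ct_refs=d_refs, ratio=ratio,
                      p_random=count / total)


def read_ct_table(table: pd.DataFrame, gene: str):
    """Split a long-format Ct table (gene, condition, replicate, Ct)
    into (control, treated) replicate arrays for one gene."""
    sub = table[table["gene"] == gene].sort_values("replicate")
    ctrl = sub.loc[sub["condition"] == "control", "Ct"].to_numpy(float)
    trt = sub.loc[sub["condition"] == "treated", "Ct"].to_numpy(float)
    return ctrl, trt
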