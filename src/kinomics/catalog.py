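"""Kinase catalog construction and tree-concordance validation.

Candidate kinases are mined from tabular profile-domain hits (a
``domtblout``-like table produced upstream; no HMM engine is run here),
assigned to families by best family-HMM hit, and then cross-validated:
a family assignment is kept (``bona_fide``) when the protein groups with
peers of its own family in a neighbor-joining tree of the candidates,
and downgraded to ``UNK`` otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .phylo import patristic_matrix

#: Pfam models accepted as protein-kinase domains.
KINASE_DOMAIN_MODELS = frozenset({"PF00069", "PF07714", "PF00481"})

HIT_COLUMNS = ["protein_id", "model_id", "model_from", "model_to",
               "model_length", "evalue", "bit_score"]


@dataclass(frozen=True)
class DomainHit:
    protein_id: str
    model_id: str
    model_from: int  # 1-based inclusive model coordinates
    model_to: int
    model_length: int
    evalue: float
    bit_score: float

    @property
    def model_coverage(self) -> float:
        return (self.model_to - self.model_from + 1) / self.model_length


def read_hits_tsv(path: str | Path) -> list[DomainHit]:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in HIT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"hit table missing columns: {missing}")
    return [DomainHit(str(r.protein_id), str(r.model_id), int(r.model_from),
                      int(r.model_to), int(r.model_length), float(r.evalue),
                      float(r.bit_score))
            for r in df.itertuples(index=False)]


def _check_hit(hit: DomainHit) -> None:
    if hit.model_length <= 0:
        raise ValueError(
            f"hit for {hit.protein_id!r} references unknown model length "
            f"({hit.model_length}) for model {hit.model_id!r}")
    if not (1 <= hit.model_from <= hit.model_to <= hit.model_length):
        raise ValueError(
            f"malformed model coordinates {hit.model_from}-{hit.model_to} "
            f"(length {hit.model_length}) for {hit.protein_id!r}")


def identify_kinases(hits: list[DomainHit],
                     min_model_coverage: float = 0.5,
                     kinase_models: frozenset[str] = KINASE_DOMAIN_MODELS
                     ) -> dict[str, int]:
    """Candidate kinases and their qualifying domain-hit counts.

    A protein qualifies when at least one hit to a kinase-domain model
    covers at least ``min_model_coverage`` of the model; the returned
    count is the number of qualifying kinase-domain hits.
    """
    counts: dict[str, int] = {}
    for hit in hits:
        if hit.model_id not in kinase_models:
            continue
        _check_hit(hit)
        if hit.model_coverage >= min_model_coverage:
            counts[hit.protein_id] = counts.get(hit.protein_id, 0) + 1
    return counts


def assign_family(family_hits: list[DomainHit],
                  evalue_cutoff: float = 1.0e-5) -> dict[str, str]:
    """Best family-HMM hit below the e-value cutoff, per protein.

    Ties are broken by (lower e-value, higher bit score, lexicographic
    model id); proteins with no passing hit are left unassigned.
    """
    best: dict[str, tuple[float, float, str]] = {}
    for hit in family_hits:
        if not hit.evalue < evalue_cutoff:
            continue
        key = (hit.evalue, -hit.bit_score, hit.model_id)
        if hit.protein_id not in best or key < best[hit.protein_id]:
            best[hit.protein_id] = key
    return {pid: key[2] for pid, key in best.items()}


def family_group(family: str) -> str:
    """Kinase group: the family-name prefix before the first underscore."""
    return family.split("_", 1)[0]


def concordance_filter(tree: dendropy.Tree, families: dict[str, str],
                       neighbor_depth: int = 1,
                       method: str = "nearest") -> dict[str, str]:
    """bona_fide/UNK status from tree grouping vs family assignment.

    ``method="nearest"`` (default): a protein is bona fide iff at least
    one of its ``neighbor_depth`` nearest other leaves (patristic
    distance, ties broken lexicographically) shares its family.
    ``method="clade"``: the smallest edge-side of the (unrooted) tree
    holding the leaf plus at least one other leaf must contain >= 50%
    same-family leaves among the others.  Singleton families are bona
    fide by default.
    """
    labels, D = patristic_matrix(tree)
    for lab in labels:
        if lab not in families:
            raise ValueError(f"tree leaf {lab!r} has no family assignment")
    sizes: dict[str, int] = {}
    for lab in labels:
        sizes[families[lab]] = sizes.get(families[lab], 0) + 1

    status: dict[str, str] = {}
    if method == "nearest":
        idx = {lab: i for i, lab in enumerate(labels)}
        for lab in labels:
            fam = families[lab]
            if sizes[fam] == 1:
                status[lab] = "bona_fide"
                continue
            others = sorted((D[idx[lab], idx[o]], o)
                            for o in labels if o != lab)
            nearest = [o for _, o in others[:neighbor_depth]]
            status[lab] = ("bona_fide"
                           if any(families[o] == fam for o in nearest)
                           else "UNK")
    elif method == "clade":
        all_leaves = set(labels)
        sides: list[frozenset[str]] = []
        for node in tree.preorder_node_iter():
            if node is tree.seed_node:
                continue
            below = frozenset(lf.taxon.label for lf in node.leaf_iter())
            sides.append(below)
            sides.append(frozenset(all_leaves - below))
        for lab in labels:
            fam = families[lab]
            if sizes[fam] == 1:
                status[lab] = "bona_fide"
                continue
            candidates = [s for s in sides if lab in s and len(s) >= 2]
            best = min(candidates,
                       key=lambda s: (len(s), tuple(sorted(s))))
            others = [o for o in best if o != lab]
            share = sum(1 for o in others if families[o] == fam)
            status[lab] = ("bona_fide" if share / len(others) >= 0.5
                           else "UNK")
    else:
        raise ValueError(f"unknown concordance method {method!r}")
    return status


def build_catalog(domain_counts: dict[str, int], families: dict[str, str],
                  status: dict[str, str] | None = None) -> pd.DataFrame:
    """Catalog table: protein_id, family, group, n_domains, status."""
    rows = []
    for pid in sorted(domain_counts):
        fam = families.get(pid)
        rows.append({
            "protein_id": pid,
            "family": fam if fam is not None else np.nan,
            "group": family_group(fam) if fam is not None else np.nan,
            "n_domains": domain_counts[pid],
            "status": (status or {}).get(pid, "candidate"),
        })
    return pd.DataFrame(rows, columns=["protein_id", "family", "group",
                                       "n_domains", "status"])
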