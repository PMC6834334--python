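"""Gene-level multimorbidity candidates and their averaged z-scores.

A gene is a candidate for a disease-pair multimorbidity in a cell type when
it belongs to both diseases' top-scoring sets there (all three for the
triple combination). Each candidate is scored by the arithmetic mean of its
propagation z-scores over the combination's diseases, and flagged as novel
when it is absent from every input disease gene set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import pandas as pd

from .propagation import TopScoringSet

__all__ = ["CandidateGene", "find_candidates", "score_candidate", "rank_and_flag"]


@dataclass
class CandidateGene:
    gene: str
    cell_type: str
    member_diseases: set[str] = field(default_factory=set)
    scores: dict[str, float] = field(default_factory=dict)  # combination label -> mean z
    novel: bool | None = None

    def combinations(self) -> list[str]:
        """All disease combinations (pairs and the full triple) this gene supports."""
        out = []
        members = sorted(self.member_diseases)
        for r in (2, 3):
            for combo in combinations(members, r):
                out.append("+".join(combo))
        return out


def find_candidates(
    sets_by_disease: dict[str, TopScoringSet], cell_type: str
) -> list[CandidateGene]:
    """Genes belonging to >= 2 top-scoring sets of the same cell type.

    Membership only; scores are attached separately.
    """
    if len(sets_by_disease) < 2:
        raise ValueError("need top-scoring sets for >= 2 diseases")
    membership: dict[str, set[str]] = {}
    for disease, ts in sets_by_disease.items():
        for g in ts.genes:
            membership.setdefault(g, set()).add(disease)
    return [
        CandidateGene(gene=g, cell_type=cell_type, member_diseases=d)
        for g, d in sorted(membership.items())
        if len(d) >= 2
    ]


def score_candidate(z_by_disease: dict[str, float], combination: list[str]) -> float:
    """Mean of the gene's z-scores over the combination's diseases."""
    missing = [d for d in combination if d not in z_by_disease]
    if missing:
        raise ValueError(f"missing z-score for disease(s) {missing}")
    return sum(z_by_disease[d] for d in combination) / len(combination)


def rank_and_flag(
    candidates: list[CandidateGene],
    disease_gene_sets: dict[str, set[str]],
) -> pd.DataFrame:
    """Rank candidates by mean combination score; flag novel genes.

    The output is sorted descending on the mean of the available
    combination scores (ties broken lexicographically on gene symbol, then
    cell type). A gene is novel iff it appears in no input disease gene
    set.
    """
    known = set().union(*disease_gene_sets.values()) if disease_gene_sets else set()
    combo_labels = sorted({c for cand in candidates for c in cand.scores})
    rows = []
    for cand in candidates:
        cand.novel = cand.gene not in known
        available = [v for v in cand.scores.values()]
        mean_score = sum(available) / len(available) if available else float("nan")
        row = {
            "cell_type": cand.cell_type,
            "gene": cand.gene,
            "member_diseases": "+".join(sorted(cand.member_diseases)),
            "mean_score": mean_score,
            "novel": cand.novel,
        }
        for label in combo_labels:
            row[label] = cand.scores.get(label, float("nan"))
        rows.append(row)
    df = pd.DataFrame(rows)
    if len(df):
        df = df.sort_values(
            ["mean_score", "gene", "cell_type"], ascending=[False, True, True]
        ).reset_index(drop=True)
    return df
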