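"""Drug-network phenotype meta-analysis.

Each screened drug carries a protein network (a gene set produced upstream by
a pathway tool and consumed here as a table).  The meta-analysis asks which
networks touch disease phenotypes: a drug x phenotype 0/1 presence matrix,
per-drug overlap with a disease gene universe, one-hot drug x gene matrices,
hierarchical clustering of drugs by their binary profiles, and a per-group
logistic-regression ranking of genes that discriminate the effect groups
(increase / decrease / no_effect on phagocytosis).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist
from sklearn.linear_model import LogisticRegression

from .errors import ValidationError

EFFECT_GROUPS = ("increase", "decrease", "no_effect")


@dataclass
class DrugNetworkSet:
    """Container for the network tables the meta-analysis consumes.

    drug_genes
        drug id -> set of network gene ids (may be empty: a drug whose
        targets produced no network still appears as an all-zero row).
    gene_phenotypes
        gene id -> set of phenotype ids the gene is annotated to.
    phenotype_clusters
        phenotype id -> cluster id (e.g. 77 phenotypes in 10 clusters).
    drug_groups
        drug id -> effect group label.
    """

    drug_genes: dict = field(default_factory=dict)
    gene_phenotypes: dict = field(default_factory=dict)
    phenotype_clusters: dict = field(default_factory=dict)
    drug_groups: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = set(self.drug_groups) - set(self.drug_genes)
        if missing:
            raise ValidationError(
                f"drugs in drug_groups missing from drug_genes: {sorted(missing)[:5]}"
            )

    def phenotype_genes(self) -> dict:
        """Invert gene->phenotypes into phenotype -> gene set."""
        out: dict = {}
        for gene, phes in self.gene_phenotypes.items():
            for p in phes:
                out.setdefault(p, set()).add(gene)
        return out


def phenotype_presence_matrix(nets: DrugNetworkSet, phenotype_ids) -> pd.DataFrame:
    """0/1 drug x phenotype matrix: 1 iff the drug network hits the phenotype.

    Entry (d, p) is 1 exactly when drug d's gene set intersects the gene set
    annotated to phenotype p.
    """
    phenotype_ids = list(phenotype_ids)
    by_phenotype = nets.phenotype_genes()
    unknown = [p for p in phenotype_ids if p not in by_phenotype]
    known_clusters = set(nets.phenotype_clusters)
    unknown = [p for p in unknown if p not in known_clusters]
    if unknown:
        raise ValidationError(f"unknown phenotype id(s): {unknown}")
    drugs = sorted(nets.drug_genes)
    mat = np.zeros((len(drugs), len(phenotype_ids)), dtype=int)
    for i, d in enumerate(drugs):
        genes = nets.drug_genes[d]
        for j, p in enumerate(phenotype_ids):
            if genes & by_phenotype.get(p, set()):
                mat[i, j] = 1
    return pd.DataFrame(mat, index=drugs, columns=phenotype_ids)


def disease_gene_overlap(nets: DrugNetworkSet, disease_gene_universe) -> dict:
    """Per-drug intersection of network genes with a disease gene universe."""
    universe = set(disease_gene_universe)
    if not universe:
        raise ValidationError("disease gene universe is empty")
    return {d: set(g) & universe for d, g in nets.drug_genes.items()}


def one_hot_matrix(overlaps: dict, gene_order) -> pd.DataFrame:
    """One-hot drug x gene matrix over an explicit (deterministic) gene order."""
    gene_order = list(gene_order)
    if len(set(gene_order)) != len(gene_order):
        dupes = [g for g in set(gene_order) if gene_order.count(g) > 1]
        raise ValidationError(f"duplicate gene(s) in gene order: {sorted(dupes)}")
    present = set().union(*overlaps.values()) if overlaps else set()
    uncovered = present - set(gene_order)
    if uncovered:
        raise ValidationError(
            f"gene order does not cover gene(s): {sorted(uncovered)[:5]}"
        )
    drugs = sorted(overlaps)
    mat = np.zeros((len(drugs), len(gene_order)), dtype=int)
    col = {g: j for j, g in enumerate(gene_order)}
    for i, d in enumerate(drugs):
        for g in overlaps[d]:
            mat[i, col[g]] = 1
    return pd.DataFrame(mat, index=drugs, columns=gene_order)


def cluster_drugs(matrix: pd.DataFrame, metric: str = "jaccard", method: str = "average"):
    """Agglomerative clustering of drugs on their binary profiles.

    Default Jaccard distance with average linkage, the natural choice for
    sparse binary set profiles (Euclidean/Ward are available through the
    arguments).  Two all-zero rows are at distance 0 by convention; an
    all-zero matrix clusters with a warning.  Returns (linkage matrix,
    leaf order as row labels); identical rows merge at height 0 and scipy's
    deterministic leaf ordering makes outputs stable.
    """
    if matrix.shape[0] < 2:
        raise ValidationError("need at least two drugs to cluster")
    x = matrix.to_numpy(dtype=bool)
    if not x.any():
        warnings.warn("all-zero matrix: every pairwise distance is 0", stacklevel=2)
    with np.errstate(invalid="ignore"):
        d = pdist(x, metric=metric)
    d = np.nan_to_num(d, nan=0.0)  # 0/0 Jaccard between empty profiles -> 0
    z = linkage(d, method=method)
    order = [matrix.index[i] for i in leaves_list(z)]
    return z, order


def group_gene_regression(
    matrix: pd.DataFrame,
    groups: dict,
    C: float = 1.0,
) -> pd.DataFrame:
    """Rank genes per effect group by one-vs-rest logistic coefficients.

    For each group with >= 2 members, fits an L2-regularized logistic
    regression (deterministic lbfgs, unpenalized intercept) of group
    membership on the 0/1 gene columns and ranks genes by descending
    coefficient, ties broken lexicographically by gene id.  ``C=np.inf``
    gives the unregularized fit.  The returned table carries columns
    (group, gene, coefficient, rank) and echoes the solver configuration in
    ``.attrs["regression_config"]``.
    """
    drugs = [d for d in matrix.index if d in groups]
    if not drugs:
        raise ValidationError("no drug in the matrix has a group label")
    sub = matrix.loc[drugs]
    labels = pd.Series({d: groups[d] for d in drugs})
    present_groups = [g for g in dict.fromkeys(labels) if (labels == g).sum() >= 2]
    skipped = sorted(set(labels) - set(present_groups))
    if skipped:
        warnings.warn(f"group(s) with <2 members skipped: {skipped}", stacklevel=2)
    if len(present_groups) < 2:
        raise ValidationError("need at least two groups with >= 2 members")
    if sub.shape[1] < 1:
        raise ValidationError("need at least one gene column")

    frames = []
    x = sub.to_numpy(dtype=float)
    for g in present_groups:
        y = (labels == g).to_numpy(dtype=int)
        model = LogisticRegression(C=C, solver="lbfgs", max_iter=5000, tol=1e-10)
        model.fit(x, y)
        coefs = model.coef_.ravel()
        tbl = pd.DataFrame(
            {"group": g, "gene": sub.columns, "coefficient": coefs}
        ).sort_values(
            ["coefficient", "gene"], ascending=[False, True], kind="stable"
        )
        tbl["rank"] = np.arange(1, len(tbl) + 1)
        frames.append(tbl)
    out = pd.concat(frames, ignore_index=True)
    out.attrs["regression_config"] = {
        "model": "one-vs-rest logistic regression",
        "penalty": "l2",
        "C": C,
        "solver": "lbfgs",
        "tol": 1e-10,
    }
    return out


def group_phenotype_fractions(
    calls: dict, presence: pd.DataFrame, clusters: dict | None = None
) -> pd.DataFrame:
    """Per-group fraction of drugs with >= 1 phenotype network association.

    ``calls`` maps drug id to effect group.  Returns one row per
    (group, scope) where scope is "overall" plus one per phenotype cluster
    when a cluster map is supplied; columns are (n_associated, group_size).
    """
    missing = [d for d in calls if d not in presence.index]
    if missing:
        raise ValidationError(
            f"drug(s) in calls missing from presence matrix: {sorted(missing)[:5]}"
        )
    scopes = {"overall": list(presence.columns)}
    if clusters:
        by_cluster: dict = {}
        for p, c in clusters.items():
            if p in presence.columns:
                by_cluster.setdefault(c, []).append(p)
        scopes.update({str(c): ps for c, ps in sorted(by_cluster.items())})

    rows = []
    groups = sorted(set(calls.values()))
    for scope, cols in scopes.items():
        hit = presence[cols].sum(axis=1) > 0 if cols else pd.Series(False, index=presence.index)
        for g in groups:
            members = [d for d, grp in calls.items() if grp == g]
            rows.append(
                {
                    "group": g,
                    "scope": scope,
                    "n_associated": int(hit.loc[members].sum()),
                    "group_size": len(members),
                }
            )
    return pd.DataFrame(rows)


def read_pair_table(path, key_col: str, value_col: str) -> dict:
    """TSV with two id columns -> {key: set of values} (drug_genes and
    gene_phenotypes input format)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in (key_col, value_col):
        if col not in df.columns:
            raise ValidationError(f"column {col!r} missing from {path}")
    out: dict = {}
    for k, v in zip(df[key_col], df[value_col]):
        out.setdefault(k, set()).add(v)
    return out
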