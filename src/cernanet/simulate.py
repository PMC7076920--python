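"""Synthetic data with planted ground truth for the ceRNA pipeline.

The generator emulates the study design the pipeline targets: a two-group
(case vs control) log2 expression array measuring lncRNAs and mRNAs only (no
miRNA expression), one lncRNA-miRNA interaction catalogue, and three partially
overlapping miRNA-mRNA target catalogues.  Truth is planted at every stage —
signed differential-expression effects, the true interaction pair sets, and a
handful of high-connectivity hub lncRNAs — so each downstream stage can be
scored against a known answer.

Defaults mirror an aqueous-humor-scale microarray study: 10 case and
10 control samples, a few hundred lncRNAs and mRNAs, ~40 miRNAs, planted
effects of 2 log2 units, gene variances drawn from an inverse-gamma
distribution (mean ~0.5, i.e. per-gene SD around 0.7 on the log2 scale).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import ExpressionMatrix
from .errors import ParameterError
from .interactions import InteractionTable

CATALOGUE_NAMES = ("target_db_1", "target_db_2", "target_db_3")
LNC_MI_CATALOGUE = "lnc_mi_db"


@dataclass(frozen=True)
class SimulationParams:
    """Knobs of the synthetic study.

    n_case, n_control : samples per group.
    n_lnc, n_mrna, n_mirna : feature counts per biotype.
    frac_de : fraction of expressed genes given a planted effect.
    effect_size : |log2FC| of every planted effect (sign randomized).
    var_shape, var_scale : inverse-gamma parameters of per-gene variances.
    catalogue_overlap : probability a true miRNA-mRNA pair is listed in any
        one of the three target catalogues (independently per catalogue).
    n_hub_lnc, hub_degree : planted hub lncRNAs and their miRNA partner count.
    lnc_mi_prob : background probability of a true lncRNA-miRNA pair.
    mi_mrna_prob : probability of a true miRNA-mRNA pair.
    decoy_frac : decoy pairs per catalogue relative to the true pair count;
        decoys never appear in all three catalogues.
    seed : master seed; every generator is a pure function of its params.
    """

    n_case: int = 10
    n_control: int = 10
    n_lnc: int = 250
    n_mrna: int = 600
    n_mirna: int = 40
    frac_de: float = 0.35
    effect_size: float = 2.0
    var_shape: float = 4.0
    var_scale: float = 1.5
    catalogue_overlap: float = 0.9
    n_hub_lnc: int = 4
    hub_degree: int = 25
    lnc_mi_prob: float = 0.06
    mi_mrna_prob: float = 0.04
    decoy_frac: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_case", "n_control", "n_lnc", "n_mrna", "n_mirna"):
            if int(getattr(self, name)) < 1:
                raise ParameterError(f"{name} must be >= 1, got {getattr(self, name)}")
        for name in ("frac_de", "catalogue_overlap", "lnc_mi_prob", "mi_mrna_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must lie in [0, 1], got {v}")
        if self.effect_size <= 0:
            raise ParameterError(f"effect_size must be > 0, got {self.effect_size}")
        for name in ("var_shape", "var_scale"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.n_hub_lnc < 0:
            raise ParameterError(f"n_hub_lnc must be >= 0, got {self.n_hub_lnc}")
        if self.n_hub_lnc > self.n_lnc:
            raise ParameterError("n_hub_lnc cannot exceed n_lnc")
        if self.hub_degree < 1:
            raise ParameterError(f"hub_degree must be >= 1, got {self.hub_degree}")
        if self.hub_degree > self.n_mirna:
            raise ParameterError(
                f"hub_degree ({self.hub_degree}) cannot exceed n_mirna ({self.n_mirna})"
            )
        if self.decoy_frac < 0:
            raise ParameterError(f"decoy_frac must be >= 0, got {self.decoy_frac}")

    def with_seed(self, seed: int) -> "SimulationParams":
        return replace(self, seed=seed)


@dataclass
class SimulationTruth:
    """Planted ground truth: what a perfect pipeline should recover."""

    de_genes: dict          # gene id -> signed planted log2FC
    true_pairs_lnc_mi: set  # (lncRNA id, miRNA id)
    true_pairs_mi_mrna: set  # (miRNA id, mRNA id)
    hub_lnc: set            # planted hub lncRNA ids


def _ids(prefix: str, n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"{prefix}{i:0{width}d}" for i in range(1, n + 1)]


def lnc_ids(p: SimulationParams) -> list[str]:
    return _ids("LNC", p.n_lnc)


def mrna_ids(p: SimulationParams) -> list[str]:
    return _ids("MRNA", p.n_mrna)


def mirna_ids(p: SimulationParams) -> list[str]:
    return _ids("MIR", p.n_mirna)


def hub_lnc_ids(p: SimulationParams) -> list[str]:
    # hubs are the first lncRNA ids; deterministic, shared by both generators
    return lnc_ids(p)[: p.n_hub_lnc]


def _plant_de(p: SimulationParams, rng: np.random.Generator) -> dict:
    """Choose planted DE genes and their signed effects.

    Hub lncRNAs are always planted (with a positive effect) so that the hub
    plant can survive the DE screen; the remainder is drawn uniformly.
    """
    genes = lnc_ids(p) + mrna_ids(p)
    hubs = hub_lnc_ids(p)
    n_de = int(round(p.frac_de * len(genes)))
    de: dict[str, float] = {}
    if n_de == 0:
        return de
    for h in hubs[:n_de]:
        de[h] = p.effect_size
    rest = [g for g in genes if g not in de]
    extra = n_de - len(de)
    if extra > 0:
        chosen = rng.choice(len(rest), size=extra, replace=False)
        signs = rng.choice([-1.0, 1.0], size=extra)
        for idx, s in zip(chosen, signs):
            de[rest[idx]] = s * p.effect_size
    return de


def generate_expression(
    params: SimulationParams,
) -> tuple[ExpressionMatrix, SimulationTruth]:
    """Simulate the log2 expression matrix with planted effects.

    Per-gene variances are inverse-gamma(var_shape, var_scale); gene g in
    sample j is N(mu_g + delta_g * 1[j is case], sigma_g^2), so the expected
    case-minus-control mean difference of a planted gene equals its signed
    effect exactly.
    """
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 0]))
    lncs, mrnas = lnc_ids(params), mrna_ids(params)
    genes = lncs + mrnas
    n_genes = len(genes)
    samples = _ids("CASE", params.n_case) + _ids("CTRL", params.n_control)
    n_samples = len(samples)

    base_mean = rng.normal(8.0, 2.0, size=n_genes)
    sigma2 = stats.invgamma.rvs(
        params.var_shape, scale=params.var_scale, size=n_genes, random_state=rng
    )
    de = _plant_de(params, rng)
    delta = np.array([de.get(g, 0.0) for g in genes])

    noise = rng.normal(size=(n_genes, n_samples)) * np.sqrt(sigma2)[:, None]
    is_case = np.array([1.0] * params.n_case + [0.0] * params.n_control)
    values = base_mean[:, None] + delta[:, None] * is_case[None, :] + noise

    matrix = ExpressionMatrix(
        values=pd.DataFrame(values, index=genes, columns=samples),
        groups=pd.Series(
            ["case"] * params.n_case + ["control"] * params.n_control,
            index=samples,
        ),
        biotype=pd.Series(
            ["lncRNA"] * params.n_lnc + ["mRNA"] * params.n_mrna, index=genes
        ),
    )
    truth = SimulationTruth(
        de_genes=de,
        true_pairs_lnc_mi=set(),
        true_pairs_mi_mrna=set(),
        hub_lnc=set(hub_lnc_ids(params)),
    )
    return matrix, truth


def generate_interactions(
    params: SimulationParams,
) -> tuple[InteractionTable, tuple[InteractionTable, ...], SimulationTruth]:
    """Simulate the interaction catalogues with planted hub lncRNAs.

    True lncRNA-miRNA pairs: every planted hub gets exactly ``hub_degree``
    distinct miRNA partners; every other (lncRNA, miRNA) pair is true with
    probability ``lnc_mi_prob``.  The single lncRNA-miRNA catalogue lists all
    true pairs.

    True miRNA-mRNA pairs arise with probability ``mi_mrna_prob``; each true
    pair enters each of the three target catalogues independently with
    probability ``catalogue_overlap``.  Decoy pairs (never true) are added to
    at most two catalogues, so at full overlap the triple intersection is
    exactly the true pair set.
    """
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 1]))
    lncs, mrnas, mirs = lnc_ids(params), mrna_ids(params), mirna_ids(params)
    hubs = hub_lnc_ids(params)

    lnc_mi: set[tuple[str, str]] = set()
    for h in hubs:
        partners = rng.choice(params.n_mirna, size=params.hub_degree, replace=False)
        lnc_mi.update((h, mirs[j]) for j in partners)
    mask = rng.random((params.n_lnc, params.n_mirna)) < params.lnc_mi_prob
    for i, j in zip(*mask.nonzero()):
        lnc_mi.add((lncs[i], mirs[j]))

    mask = rng.random((params.n_mirna, params.n_mrna)) < params.mi_mrna_prob
    mi_mrna = {(mirs[i], mrnas[j]) for i, j in zip(*mask.nonzero())}

    true_list = sorted(mi_mrna)
    catalogues: list[set[tuple[str, str]]] = [set(), set(), set()]
    present = rng.random((len(true_list), 3)) < params.catalogue_overlap
    for row, pair in zip(present, true_list):
        for c in range(3):
            if row[c]:
                catalogues[c].add(pair)

    n_decoys = int(round(params.decoy_frac * len(true_list)))
    decoys: set[tuple[str, str]] = set()
    while len(decoys) < n_decoys:
        i = int(rng.integers(params.n_mirna))
        j = int(rng.integers(params.n_mrna))
        pair = (mirs[i], mrnas[j])
        if pair not in mi_mrna:
            decoys.add(pair)
    for pair in sorted(decoys):
        # each decoy lands in one or two catalogues, never all three
        k = int(rng.integers(1, 3))
        for c in rng.choice(3, size=k, replace=False):
            catalogues[int(c)].add(pair)

    lnc_mi_table = InteractionTable(
        kind="lnc_mi", pairs=lnc_mi, catalogue=LNC_MI_CATALOGUE
    )
    cat_tables = tuple(
        InteractionTable(kind="mi_mrna", pairs=catalogues[c], catalogue=CATALOGUE_NAMES[c])
        for c in range(3)
    )
    truth = SimulationTruth(
        de_genes={},
        true_pairs_lnc_mi=lnc_mi,
        true_pairs_mi_mrna=mi_mrna,
        hub_lnc=set(hubs),
    )
    return lnc_mi_table, cat_tables, truth


def generate_annotation(
    genes, n_terms: int, term_size_range: tuple[int, int], seed: int
) -> dict:
    """Random flat term annotation: term id -> (term name, gene id set)."""
    genes = sorted(genes)
    if not genes:
        raise ParameterError("gene set for annotation must be non-empty")
    lo, hi = term_size_range
    if lo < 1 or hi < lo:
        raise ParameterError(f"invalid term_size_range {term_size_range}")
    if hi > len(genes):
        raise ParameterError(
            f"term sizes up to {hi} exceed the {len(genes)}-gene universe"
        )
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    annotation = {}
    for t in range(1, n_terms + 1):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(len(genes), size=size, replace=False)
        term_id = f"TERM{t:04d}"
        annotation[term_id] = (f"synthetic term {t}", {genes[i] for i in members})
    return annotation


# ---------------------------------------------------------------------------
# Standard input files
# ---------------------------------------------------------------------------

def write_expression(matrix: ExpressionMatrix, expr_path, groups_path, biotype_path):
    df = matrix.values.copy()
    df.index.name = "gene_id"
    df.to_csv(expr_path, sep="\t")  # default shortest-repr floats round-trip exactly
    pd.DataFrame(
        {"sample_id": matrix.groups.index, "group": matrix.groups.values}
    ).to_csv(groups_path, sep="\t", index=False)
    pd.DataFrame(
        {"gene_id": matrix.biotype.index, "biotype": matrix.biotype.values}
    ).to_csv(biotype_path, sep="\t", index=False)


def write_interactions(table: InteractionTable, path) -> None:
    rows = sorted(table.pairs)
    pd.DataFrame(
        {
            "regulator_id": [r for r, _ in rows],
            "target_id": [t for _, t in rows],
            "catalogue": table.catalogue,
        }
    ).to_csv(path, sep="\t", index=False)


def write_annotation(annotation: dict, path) -> None:
    rows = []
    for term_id in sorted(annotation):
        name, members = annotation[term_id]
        for g in sorted(members):
            rows.append((term_id, name, g))
    pd.DataFrame(rows, columns=["term_id", "term_name", "gene_id"]).to_csv(
        path, sep="\t", index=False
    )


def write_all_inputs(params: SimulationParams, outdir, n_terms: int = 50,
                     term_size_range: tuple[int, int] = (10, 60)) -> dict:
    """Generate every pipeline input under ``outdir``; returns the path map."""
    os.makedirs(outdir, exist_ok=True)
    matrix, truth_expr = generate_expression(params)
    lnc_mi, cats, truth_int = generate_interactions(params)
    annotation = generate_annotation(
        mrna_ids(params), n_terms, term_size_range, params.seed
    )
    paths = {
        "expression": os.path.join(outdir, "expression.tsv"),
        "groups": os.path.join(outdir, "groups.tsv"),
        "biotype": os.path.join(outdir, "biotype.tsv"),
        "lnc_mi": os.path.join(outdir, "lnc_mi_interactions.tsv"),
        "annotation": os.path.join(outdir, "annotation.tsv"),
    }
    write_expression(matrix, paths["expression"], paths["groups"], paths["biotype"])
    write_interactions(lnc_mi, paths["lnc_mi"])
    for i, cat in enumerate(cats, start=1):
        key = f"mi_mrna_{i}"
        paths[key] = os.path.join(outdir, f"mi_mrna_{cat.catalogue}.tsv")
        write_interactions(cat, paths[key])
    write_annotation(annotation, paths["annotation"])
    return paths
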