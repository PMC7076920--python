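"""Interaction catalogues and the consensus intersection.

The ceRNA screen uses two kinds of interaction evidence: a lncRNA-miRNA
catalogue (one source) and three independent miRNA-mRNA target catalogues.
Only miRNA-mRNA pairs predicted by all three catalogues are retained
(the consensus), and both edge sets are then restricted to differentially
expressed lncRNAs and mRNAs.  miRNAs are never filtered by expression: the
platform the pipeline targets measures lncRNAs and mRNAs only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ContractError, LoadError

logger = logging.getLogger(__name__)

KINDS = ("lnc_mi", "mi_mrna")


def normalize_mirna(name: str) -> str:
    """Case-insensitive miRNA id normalization; prefixes kept as written."""
    return name.strip().lower() if name.lower().startswith("hsa-") else name.strip()


@dataclass
class InteractionTable:
    """A deduplicated set of typed regulator->target pairs from one source."""

    kind: str                     # "lnc_mi" or "mi_mrna"
    pairs: set = field(default_factory=set)
    catalogue: str = ""

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ContractError(f"unknown interaction kind '{self.kind}'")
        for reg, tgt in self.pairs:
            if not reg or not tgt:
                raise ContractError("empty identifier in interaction pair")

    def __len__(self) -> int:
        return len(self.pairs)

    def regulators(self) -> set:
        return {r for r, _ in self.pairs}

    def targets(self) -> set:
        return {t for _, t in self.pairs}


def load_interaction_table(path, kind: str) -> InteractionTable:
    """Read a regulator/target/catalogue TSV; duplicates collapse with a log."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"regulator_id", "target_id"}
    if not required.issubset(df.columns):
        raise LoadError(
            f"{path}: expected columns regulator_id, target_id, catalogue; "
            f"found {list(df.columns)}"
        )
    bad = df.index[df["regulator_id"].isna() | df["target_id"].isna()]
    if len(bad):
        # +2: header line and 1-based numbering
        raise LoadError(f"{path}: malformed row at line {bad[0] + 2}")
    pairs = list(zip(df["regulator_id"], df["target_id"]))
    unique = set(pairs)
    if len(unique) < len(pairs):
        logger.warning(
            "%s: %d duplicate pair(s) collapsed", path, len(pairs) - len(unique)
        )
    catalogue = ""
    if "catalogue" in df.columns and len(df):
        catalogue = str(df["catalogue"].iloc[0])
    return InteractionTable(kind=kind, pairs=unique, catalogue=catalogue)


def intersect_catalogues(tables) -> InteractionTable:
    """Consensus miRNA-mRNA set: pairs predicted by all three catalogues."""
    tables = list(tables)
    if len(tables) != 3:
        raise ContractError(f"exactly three catalogues required, got {len(tables)}")
    for t in tables:
        if t.kind != "mi_mrna":
            raise ContractError(
                f"catalogue '{t.catalogue}' has kind '{t.kind}', expected mi_mrna"
            )
    consensus = tables[0].pairs & tables[1].pairs & tables[2].pairs
    return InteractionTable(kind="mi_mrna", pairs=consensus, catalogue="consensus")


def restrict_to_de(
    lnc_mi: InteractionTable, consensus: InteractionTable, de_sets
) -> tuple[InteractionTable, InteractionTable]:
    """Keep pairs whose measured endpoint is differentially expressed.

    lncRNA-miRNA pairs keep only DE lncRNA regulators; consensus miRNA-mRNA
    pairs keep only DE mRNA targets.  miRNAs pass through unfiltered (they
    are unmeasured).
    """
    de_lnc, de_mrna = de_sets.de_lnc, de_sets.de_mrna
    lnc_mi_de = InteractionTable(
        kind="lnc_mi",
        pairs={p for p in lnc_mi.pairs if p[0] in de_lnc},
        catalogue=lnc_mi.catalogue,
    )
    mi_mrna_de = InteractionTable(
        kind="mi_mrna",
        pairs={p for p in consensus.pairs if p[1] in de_mrna},
        catalogue=consensus.catalogue,
    )
    return lnc_mi_de, mi_mrna_de


def negative_correlation_filter(
    pairs: InteractionTable,
    expr_regulator: pd.DataFrame,
    expr_target: pd.DataFrame,
    threshold: float = 0.0,
) -> InteractionTable:
    """Optional ceRNA-pair filter: keep pairs with Pearson r < threshold.

    Disabled by default in the pipeline: the targeted platform measures no
    miRNA expression, so regulator-target correlations involving miRNAs
    cannot be computed from the study's own data.  Provided for datasets
    where both endpoints are profiled.
    """
    kept = set()
    for reg, tgt in pairs.pairs:
        if reg not in expr_regulator.index or tgt not in expr_target.index:
            continue
        r = np.corrcoef(
            expr_regulator.loc[reg].to_numpy(float),
            expr_target.loc[tgt].to_numpy(float),
        )[0, 1]
        if r < threshold:
            kept.add((reg, tgt))
    return InteractionTable(kind=pairs.kind, pairs=kept, catalogue=pairs.catalogue)
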