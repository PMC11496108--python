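"""Genome-scale-model reaction scoring from gene-level z-scores.

Reads reaction-gene associations from an SBML model (fbc gene-product
associations, with a fallback to GENE_ASSOCIATION notes), pools gene z-scores
per reaction by summation, collapses reactions sharing identical gene sets to
one representative, and flags pooled z > 3 as significant.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass

import libsbml
import pandas as pd

__all__ = ["ReactionScore", "load_gene_associations", "pool_reaction_z"]


@dataclass
class ReactionScore:
    reaction: str
    genes: frozenset[str]
    pooled_z: float
    significant: bool
    n_missing: int = 0  # genes absent from the z table (contributed 0)
    represents: tuple[str, ...] = ()  # other reactions with the same gene set


def _collect_gene_refs(assoc, out: set[str]) -> None:
    if assoc is None:
        return
    if assoc.isFbcAnd() or assoc.isFbcOr():
        for i in range(assoc.getNumAssociations()):
            _collect_gene_refs(assoc.getAssociation(i), out)
    elif assoc.isGeneProductRef():
        out.add(assoc.getGeneProduct())


def load_gene_associations(sbml_path) -> dict[str, set[str]]:
    """Map reaction id -> associated gene set; empty-set reactions excluded.

    Logical structure (AND/OR) of the associations is flattened to the set of
    referenced genes, matching a summed pooling rule. Unparseable
    associations are skipped with a warning, not fatal.
    """
    doc = libsbml.readSBMLFromFile(str(sbml_path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        raise ValueError(
            f"unreadable SBML: {doc.getError(0).getMessage().strip()}"
        )
    model = doc.getModel()
    if model is None:
        raise ValueError("SBML file contains no model")

    gene_label = {}
    fbc_model = model.getPlugin("fbc")
    if fbc_model is not None:
        for i in range(fbc_model.getNumGeneProducts()):
            gp = fbc_model.getGeneProduct(i)
            gene_label[gp.getId()] = gp.getLabel() or gp.getId()

    out: dict[str, set[str]] = {}
    for i in range(model.getNumReactions()):
        rxn = model.getReaction(i)
        genes: set[str] = set()
        try:
            fbc = rxn.getPlugin("fbc")
            gpa = fbc.getGeneProductAssociation() if fbc is not None else None
            if gpa is not None:
                refs: set[str] = set()
                _collect_gene_refs(gpa.getAssociation(), refs)
                genes = {gene_label.get(g, g) for g in refs}
            elif rxn.isSetNotes():
                notes = rxn.getNotesString()
                m = re.search(r"GENE_ASSOCIATION:\s*([^<]+)", notes)
                if m:
                    genes = {
                        g
                        for g in re.split(r"\band\b|\bor\b|[()\s]+", m.group(1))
                        if g
                    }
        except Exception as err:  # noqa: BLE001
            warnings.warn(
                f"reaction {rxn.getId()}: unparseable gene association ({err})",
                stacklevel=2,
            )
            continue
        if genes:
            out[rxn.getId()] = genes
    return out


def pool_reaction_z(
    associations: dict[str, set[str]],
    gene_z: dict[str, float],
    z_cutoff: float = 3.0,
    normalize: bool = False,
) -> list[ReactionScore]:
    """Pooled z per reaction: sum of gene z-scores over associated genes.

    Genes absent from ``gene_z`` contribute 0 and are counted in
    ``n_missing``. Reactions with identical gene sets are collapsed to the
    lexicographically smallest reaction id. ``normalize=True`` divides by
    sqrt(k) (Stouffer-style) instead of using the raw sum. Significance is
    strict: pooled z > ``z_cutoff``.
    """
    for g, z in gene_z.items():
        if not math.isfinite(z):
            raise ValueError(f"non-finite z-score for gene {g}")

    by_geneset: dict[frozenset, list[str]] = {}
    for rxn, genes in associations.items():
        by_geneset.setdefault(frozenset(genes), []).append(rxn)

    scores = []
    for genes, rxns in by_geneset.items():
        rxns = sorted(rxns)
        z = sum(gene_z.get(g, 0.0) for g in genes)
        missing = sum(1 for g in genes if g not in gene_z)
        if normalize and genes:
            z /= math.sqrt(len(genes))
        scores.append(
            ReactionScore(
                reaction=rxns[0],
                genes=genes,
                pooled_z=z,
                significant=z > z_cutoff,
                n_missing=missing,
                represents=tuple(rxns[1:]),
            )
        )
    return sorted(scores, key=lambda s: s.reaction)


def scores_to_frame(scores: list[ReactionScore]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "reaction": s.reaction,
            "genes": ";".join(sorted(s.genes)),
            "pooled_z": s.pooled_z,
            "significant": s.significant,
            "n_missing": s.n_missing,
            "represents": ";".join(s.represents),
        }
        for s in scores
    )
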