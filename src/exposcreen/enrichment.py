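"""Toxin -> protein -> pathway enrichment for flagged associations.

Once a disease has a set of flagged toxicants, two Fisher-exact stages
suggest mechanism:

1. *Protein enrichment*: for each protein in a toxin-protein
   interaction map, does the number of flagged toxicants hitting it
   exceed chance expectation among the screenable background toxins?
   (One-sided, enrichment direction; BH-FDR across proteins.)
2. *Pathway enrichment*: the set of proteins touched by the flagged
   toxicants is tested, unordered-gene-list style, against GMT gene-set
   libraries (GO BP/MF, KEGG, WikiPathways conventions), one BH family
   per library.

The background universe for protein tests is the intersection of the
interaction map's toxins with the exposure matrix columns — "chance"
means chance among chemicals the screen could actually have flagged.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSetLibrary",
    "ToxinProteinMap",
    "bh_fdr",
    "fisher_exact_right",
    "pathway_enrichment",
    "protein_enrichment",
    "read_gmt",
    "read_toxin_protein_map",
    "write_gmt",
]

RESULT_COLUMNS = ["entity", "a", "b", "c", "d", "odds_ratio", "p_value", "q_value"]


@dataclass
class ToxinProteinMap:
    """Deduplicated toxin-protein interaction pairs with index maps."""

    pairs: pd.DataFrame  # columns toxin_id, protein_symbol
    toxin_to_proteins: dict = field(default_factory=dict)
    protein_to_toxins: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        pairs = self.pairs[["toxin_id", "protein_symbol"]].astype(str)
        if (pairs["protein_symbol"].str.len() == 0).any():
            raise ValueError("empty protein symbol in toxin-protein map")
        pairs["protein_symbol"] = pairs["protein_symbol"].str.upper()
        pairs = pairs.drop_duplicates()
        self.pairs = pairs.reset_index(drop=True)
        self.toxin_to_proteins = {
            t: set(g["protein_symbol"]) for t, g in pairs.groupby("toxin_id")
        }
        self.protein_to_toxins = {
            p: set(g["toxin_id"]) for p, g in pairs.groupby("protein_symbol")
        }

    @property
    def toxins(self) -> set:
        return set(self.toxin_to_proteins)

    @property
    def proteins(self) -> set:
        return set(self.protein_to_toxins)


def read_toxin_protein_map(path) -> ToxinProteinMap:
    """Read a two-column TSV ``toxin_id<TAB>protein_symbol``."""
    pairs = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("toxin_id", "protein_symbol"):
        if col not in pairs.columns:
            raise ValueError(f"toxin-protein map is missing required column: {col}")
    return ToxinProteinMap(pairs)


@dataclass
class GeneSetLibrary:
    """Named gene sets plus the universe they are tested against."""

    name: str
    sets: dict  # pathway name -> set of uppercased gene symbols
    universe_size: int = 0

    def __post_init__(self) -> None:
        self.sets = {
            str(k): {str(g).upper() for g in v} for k, v in self.sets.items() if len(v)
        }
        union = set().union(*self.sets.values()) if self.sets else set()
        if self.universe_size <= 0:
            # Convention of unordered-list enrichment tools: the universe is
            # the distinct genes of the loaded library.
            self.universe_size = len(union)
        if self.universe_size < len(union):
            raise ValueError("universe_size smaller than the union of the gene sets")
        self.universe = union


def read_gmt(path, name=None) -> GeneSetLibrary:
    """Read a GMT file (set name, description, gene symbols...)."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                continue
            sets[fields[0]] = {g for g in fields[2:] if g}
    return GeneSetLibrary(name=name or str(path), sets=sets)


def write_gmt(library: GeneSetLibrary, path) -> None:
    with open(path, "w") as fh:
        for pname, genes in library.sets.items():
            fh.write("\t".join([pname, library.name] + sorted(genes)) + "\n")


def fisher_exact_right(a: int, b: int, c: int, d: int) -> float:
    """Right-tailed Fisher exact p for the 2x2 table [[a, b], [c, d]].

    The hypergeometric tail P(X >= a) with population a+b+c+d, a+c
    successes and draws of size a+b — the enrichment direction.
    Degenerate margins (an all-zero row or column) give p = 1 with a
    warning.
    """
    cells = (a, b, c, d)
    if any(x < 0 or x != int(x) for x in cells):
        raise ValueError("table cells must be non-negative integers")
    a, b, c, d = (int(x) for x in cells)
    if (a + b == 0) or (a + c == 0) or (b + d == 0) or (c + d == 0):
        if a + b + c + d == 0 or (a + b == 0 and c + d == 0):
            warnings.warn("all-zero margins: p = 1", UserWarning, stacklevel=2)
        return 1.0
    return float(hypergeom.sf(a - 1, a + b + c + d, a + c, a + b))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving with input."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _sample_odds_ratio(a, b, c, d) -> float:
    if b * c == 0:
        return float("inf") if a * d > 0 else float("nan")
    return (a * d) / (b * c)


def protein_enrichment(flagged_toxins, toxin_protein_map: ToxinProteinMap, background=None) -> pd.DataFrame:
    """Per-protein enrichment of flagged toxicants among interactors.

    For protein P with interactor set I (restricted to the background):
    a = |flagged & I|, b = |flagged| - a, c = |I| - a, d = the rest of
    the background.  Proteins untouched by any flagged toxin (a = 0)
    are skipped.  ``background`` defaults to every toxin in the map;
    callers screening exposures should pass the map-toxins intersected
    with the exposure-matrix columns.
    """
    if background is None:
        background = toxin_protein_map.toxins
    background = set(background) & toxin_protein_map.toxins
    flagged = set(flagged_toxins)
    outside = flagged - background
    if outside:
        logger.warning(
            "%d flagged toxin(s) outside the background dropped: %s",
            len(outside),
            sorted(outside)[:10],
        )
        flagged &= background
    if not flagged:
        warnings.warn("no flagged toxins in background: empty result", UserWarning, stacklevel=2)
        return pd.DataFrame(columns=RESULT_COLUMNS)

    n_bg = len(background)
    n_flag = len(flagged)
    rows = []
    for protein in sorted(toxin_protein_map.proteins):
        interactors = toxin_protein_map.protein_to_toxins[protein] & background
        a = len(flagged & interactors)
        if a == 0:
            continue
        b = n_flag - a
        c = len(interactors) - a
        d = n_bg - n_flag - c
        rows.append(
            {
                "entity": protein,
                "a": a,
                "b": b,
                "c": c,
                "d": d,
                "odds_ratio": _sample_odds_ratio(a, b, c, d),
                "p_value": fisher_exact_right(a, b, c, d),
            }
        )
    result = pd.DataFrame(rows, columns=RESULT_COLUMNS[:-1])
    if not result.empty:
        result["q_value"] = bh_fdr(result["p_value"].to_numpy())
    else:
        result["q_value"] = []
    return result[RESULT_COLUMNS]


def pathway_enrichment(protein_set, library: GeneSetLibrary) -> pd.DataFrame:
    """Fisher-exact pathway enrichment of an unordered protein list.

    a = |set & pathway|, b = in-universe set members outside the
    pathway, c = pathway genes outside the set, d = universe remainder.
    Pathways with no overlap are skipped; BH is applied per library.
    """
    query = {str(p).upper() for p in protein_set} & library.universe
    if not query:
        warnings.warn(
            "protein set has zero overlap with the library universe", UserWarning, stacklevel=2
        )
        return pd.DataFrame(columns=RESULT_COLUMNS)

    n_universe = library.universe_size
    rows = []
    for pname in sorted(library.sets):
        genes = library.sets[pname]
        a = len(query & genes)
        if a == 0:
            continue
        b = len(query) - a
        c = len(genes) - a
        d = n_universe - len(query) - c
        rows.append(
            {
                "entity": pname,
                "a": a,
                "b": b,
                "c": c,
                "d": d,
                "odds_ratio": _sample_odds_ratio(a, b, c, d),
                "p_value": fisher_exact_right(a, b, c, d),
            }
        )
    result = pd.DataFrame(rows, columns=RESULT_COLUMNS[:-1])
    if not result.empty:
        result["q_value"] = bh_fdr(result["p_value"].to_numpy())
    else:
        result["q_value"] = []
    return result[RESULT_COLUMNS].sort_values("p_value", kind="mergesort").reset_index(drop=True)
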