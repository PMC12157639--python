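"""Gene-set enrichment of module memberships by one-tailed Fisher's exact test.

Reads GMT-format collections (cell-type marker lists, ontologies), builds the
2x2 overlap table of a query protein set against each gene set restricted to
a background universe (by default every protein detected in the analysed
matrix — enrichment conditions on detectability), and reports the
hypergeometric upper-tail p with BH correction across the grid.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .diffstats import bh_adjust, star_annotation

__all__ = ["read_gmt", "fisher_enrichment", "enrich_modules", "GeneSetCollection"]


@dataclass
class GeneSetCollection:
    sets: dict[str, set[str]]
    descriptions: dict[str, str]
    source: str = ""

    def __len__(self) -> int:
        return len(self.sets)


def normalize_symbol(symbol: str, isoform_delim: str = "|") -> str:
    """Upper-case a gene symbol, stripping anything after the isoform delimiter."""
    s = symbol.strip()
    if isoform_delim and isoform_delim in s:
        s = s.split(isoform_delim, 1)[0]
    return s.upper()


def read_gmt(path, isoform_delim: str = "|") -> GeneSetCollection:
    """Parse a GMT file: one set per line, name TAB description TAB members...

    Duplicate members collapse; empty member fields drop; a line with fewer
    than three fields is an error naming its line number.
    """
    sets: dict[str, set[str]] = {}
    desc: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line {lineno}: expected >= 3 tab-separated fields")
        name = fields[0].strip()
        members = {normalize_symbol(m, isoform_delim) for m in fields[2:] if m.strip()}
        if not members:
            raise ValueError(f"malformed GMT line {lineno}: set {name!r} has no members")
        sets[name] = members
        desc[name] = fields[1].strip()
    return GeneSetCollection(sets=sets, descriptions=desc, source=str(path))


def fisher_enrichment(
    query_genes,
    gene_set,
    background,
    haldane: bool = True,
) -> dict:
    """One-tailed (enrichment) Fisher's exact test of query vs gene set.

    All three inputs are gene collections; query and set are intersected with
    the background first.  p = hypergeometric upper tail P(X >= overlap).
    The odds ratio uses a 0.5 Haldane correction only when a cell is zero.
    """
    background = set(background)
    if not background:
        raise ValueError("background must be nonempty")
    query = set(query_genes) & background
    gset = set(gene_set) & background
    overlap = query & gset
    a = len(overlap)
    b = len(query) - a
    c = len(gset) - a
    d = len(background) - a - b - c
    # upper tail: P(X >= a) with X ~ Hypergeom(N, K=|set|, n=|query|)
    p = float(stats.hypergeom.sf(a - 1, len(background), len(gset), len(query)))
    if 0 in (a, b, c, d) and haldane:
        orr = (a + 0.5) * (d + 0.5) / ((b + 0.5) * (c + 0.5))
    elif b * c == 0:
        orr = np.inf
    else:
        orr = a * d / (b * c)
    return {
        "overlap": a,
        "query_size": len(query),
        "set_size": len(gset),
        "background_size": len(background),
        "odds_ratio": float(orr),
        "p": min(max(p, 0.0), 1.0),
        "overlap_genes": ";".join(sorted(overlap)),
    }


def enrich_modules(
    labels: pd.Series,
    collection: GeneSetCollection,
    background: set[str] | None = None,
    isoform_delim: str = "|",
) -> pd.DataFrame:
    """Every module x every gene set Fisher enrichment, BH across the grid.

    ``labels`` maps feature symbols to module ids (0 = unassigned).  The
    default background is every labelled feature including unassigned ones.
    """
    norm = pd.Index([normalize_symbol(str(f), isoform_delim) for f in labels.index])
    lab = pd.Series(labels.to_numpy(), index=norm)
    bg = set(background) if background is not None else set(norm)
    rows = []
    for m in sorted(int(x) for x in lab.unique() if x > 0):
        query = set(lab.index[lab == m])
        for name, members in collection.sets.items():
            row = fisher_enrichment(query, members, bg)
            row.update({"module": f"M{m}", "gene_set": name})
            rows.append(row)
    table = pd.DataFrame(rows)
    if len(table):
        table["q"] = bh_adjust(table["p"].to_numpy())
        table["stars"] = table["p"].map(star_annotation)
        cols = [
            "module", "gene_set", "overlap", "query_size", "set_size",
            "background_size", "odds_ratio", "p", "q", "stars", "overlap_genes",
        ]
        table = table[cols]
    return table
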