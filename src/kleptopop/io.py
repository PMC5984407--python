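"""File formats: genotype CSV, locus/rules YAML, AFLP CSV, newick, matrices.

Genotype tables are plain CSV — one row per individual with ``id`` and
``site`` columns (optionally ``mtdna_unisexual``) followed by one column per
locus; a cell holds the slash-separated distinct allele sizes in bp
(``133/177/181``) and an empty cell means missing data.  Allele binning is
assumed done upstream.  A GenePop export is provided for diploid LL subsets.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import yaml
from skbio import TreeNode

from .model import (
    AflpMatrix,
    Dataset,
    DistanceMatrix,
    IndividualRecord,
    KleptopopError,
    LocusDef,
    MultisetGenotype,
)
from .partition import DiagnosticRuleTable


def _parse_range(value):
    if value is None:
        return None
    lo, hi = value
    return (int(lo), int(hi))


def read_locus_config(path) -> tuple[list[LocusDef], pd.DataFrame | None]:
    """Read loci (and optionally sites) from a YAML config."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    loci = [
        LocusDef(
            name=entry["name"],
            motif_length=int(entry["motif_length"]),
            j_range=_parse_range(entry.get("j_range")),
            l_range=_parse_range(entry.get("l_range")),
            u_range=_parse_range(entry.get("u_range")),
        )
        for entry in raw["loci"]
    ]
    sites = None
    if "sites" in raw:
        sites = pd.DataFrame(raw["sites"])[["site", "latitude", "longitude"]]
    return loci, sites


def write_locus_config(loci: list[LocusDef], path, sites: pd.DataFrame | None = None):
    data: dict = {
        "loci": [
            {
                "name": l.name,
                "motif_length": l.motif_length,
                **({"j_range": list(l.j_range)} if l.j_range else {}),
                **({"l_range": list(l.l_range)} if l.l_range else {}),
                **({"u_range": list(l.u_range)} if l.u_range else {}),
            }
            for l in loci
        ]
    }
    if sites is not None:
        data["sites"] = sites.to_dict(orient="records")
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def read_rule_table(path) -> DiagnosticRuleTable:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return DiagnosticRuleTable(
        consensus={k: tuple(v) for k, v in raw["consensus"].items()},
        diagnostics={
            g: tuple((iso, int(a)) for iso, a in pairs)
            for g, pairs in raw["diagnostics"].items()
        },
        consensus_group=raw.get("consensus_group", "B"),
    )


def write_rule_table(rules: DiagnosticRuleTable, path):
    data = {
        "consensus": {k: list(v) for k, v in rules.consensus.items()},
        "diagnostics": {
            g: [[iso, a] for iso, a in pairs]
            for g, pairs in rules.diagnostics.items()
        },
        "consensus_group": rules.consensus_group,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def _parse_cell(cell, row_id, locus) -> tuple[int, ...]:
    if cell is None or (isinstance(cell, float) and np.isnan(cell)):
        return ()
    text = str(cell).strip()
    if not text:
        return ()
    alleles = []
    for part in text.split("/"):
        part = part.strip()
        try:
            alleles.append(int(part))
        except ValueError:
            raise KleptopopError(
                f"non-numeric allele {part!r} at row {row_id!r}, column {locus!r}"
            ) from None
    return tuple(sorted(set(alleles)))


RESERVED_COLUMNS = ("id", "site", "mtdna_unisexual")


def read_genotype_table(path, loci: list[LocusDef], sites: pd.DataFrame | None = None) -> Dataset:
    """Read a genotype CSV against a declared locus panel."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if "id" not in df.columns or "site" not in df.columns:
        raise KleptopopError("genotype table needs 'id' and 'site' columns")
    known = {l.name for l in loci}
    locus_cols = [c for c in df.columns if c not in RESERVED_COLUMNS]
    unknown = [c for c in locus_cols if c not in known]
    if unknown:
        raise KleptopopError(f"unknown locus column(s): {unknown}")
    individuals = []
    for _, row in df.iterrows():
        genotypes = {}
        for locus in locus_cols:
            alleles = _parse_cell(row[locus], row["id"], locus)
            if alleles:
                genotypes[locus] = MultisetGenotype(locus, alleles)
        mtdna = None
        if "mtdna_unisexual" in df.columns and str(row["mtdna_unisexual"]).strip():
            mtdna = str(row["mtdna_unisexual"]).strip().lower() in ("1", "true", "yes")
        individuals.append(
            IndividualRecord(
                id=row["id"], site=row["site"], genotypes=genotypes,
                mtdna_unisexual=mtdna,
            )
        )
    return Dataset(individuals=individuals, loci=list(loci), sites=sites)


def write_genotype_table(dataset: Dataset, path):
    rows = []
    for ind in dataset.individuals:
        row = {"id": ind.id, "site": ind.site}
        if ind.mtdna_unisexual is not None:
            row["mtdna_unisexual"] = str(ind.mtdna_unisexual).lower()
        for locus in dataset.loci:
            g = ind.genotypes.get(locus.name)
            row[locus.name] = (
                "/".join(str(a) for a in g.observed_alleles) if g else ""
            )
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_aflp_matrix(path) -> AflpMatrix:
    """Read an AFLP presence/absence CSV (first column: individual ids)."""
    try:
        df = pd.read_csv(path, index_col=0)
    except pd.errors.EmptyDataError:
        raise KleptopopError("empty AFLP file") from None
    if df.shape[1] == 0 or df.shape[0] == 0:
        raise KleptopopError("AFLP matrix has no bands or no individuals")
    values = df.to_numpy()
    if not np.isin(values, (0, 1)).all():
        raise KleptopopError("AFLP matrix entries must be 0 or 1")
    return AflpMatrix(
        individuals=[str(i) for i in df.index],
        bands=[str(c) for c in df.columns],
        presence=values,
    )


def write_aflp_matrix(aflp: AflpMatrix, path):
    pd.DataFrame(aflp.presence, index=aflp.individuals, columns=aflp.bands).to_csv(
        path
    )


def write_matrix(matrix: DistanceMatrix, path):
    matrix.to_dataframe().to_csv(path)


def read_matrix(path) -> DistanceMatrix:
    return DistanceMatrix.from_dataframe(pd.read_csv(path, index_col=0))


def write_newick(tree: TreeNode, path):
    tree.write(str(path), format="newick")


def read_newick(path) -> TreeNode:
    return TreeNode.read(str(path), format="newick")


def write_genepop(dataset: Dataset, path, title="LL allele frequencies export"):
    """GenePop export of the diploid LL individuals (L-amplifying loci).

    Alleles are coded as 3-digit repeat indices relative to 1; homozygotes
    are written with the single observed allele doubled.
    """
    ll = [ind for ind in dataset.individuals if ind.biotype == "LL"]
    if not ll:
        raise KleptopopError("no LL individuals to export")
    loci = [l for l in dataset.loci if l.l_range is not None or not l.discriminating]
    with open(path, "w") as fh:
        fh.write(title + "\n")
        for locus in loci:
            fh.write(locus.name + "\n")
        by_site: dict[str, list] = {}
        for ind in ll:
            by_site.setdefault(ind.site, []).append(ind)
        for site, inds in sorted(by_site.items()):
            fh.write("POP\n")
            for ind in inds:
                codes = []
                for locus in loci:
                    g = ind.genotypes.get(locus.name)
                    alleles = list(g.observed_alleles) if g else []
                    if not alleles:
                        codes.append("000000")
                        continue
                    if len(alleles) == 1:
                        alleles = alleles * 2
                    a, b = alleles[:2]
                    code = f"{_repeat_code(a, locus):03d}{_repeat_code(b, locus):03d}"
                    codes.append(code)
                fh.write(f"{site}_{ind.id}, " + " ".join(codes) + "\n")


def _repeat_code(allele: int, locus: LocusDef) -> int:
    return max(1, allele // locus.motif_length % 1000)
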