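"""Final accounting: DEG coding-class tree, Venn tables and the
feature x DE-status cross-tabulation.

The hub record is the *gene table*: one row per gene with its coding
class, genome-hit flag, per-genotype detection, meiocyte exclusivity,
sRNA-similarity, TE and NAT flags, and DE status.  Everything here is
percentage arithmetic over that table (or over shipped reference count
fixtures), with a fixed rounding convention: percentages are reported
to two decimals, rounded half-up.
"""

from __future__ import annotations

import importlib.resources
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from meiolnc.quant import proportion_test

CROSSTAB_FEATURES = ("genome_hit", "three_genotypes",
                     "three_genotypes_and_genome_hit", "srna_similarity",
                     "contains_transposons")
STRATA = ("all", "meiocyte_exclusive", "shared")


def percentage(numerator: int, denominator: int) -> float:
    """100 * n / d, rounded half-up to two decimals."""
    if denominator == 0:
        raise ZeroDivisionError("percentage undefined for zero denominator")
    frac = Decimal(100) * Decimal(int(numerator)) / Decimal(int(denominator))
    return float(frac.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def load_fixture(name: str) -> pd.DataFrame:
    """Load a shipped reference-count fixture by file name."""
    ref = importlib.resources.files("meiolnc.data.fixtures") / name
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", comment="#")


# ---------------------------------------------------------------------------
# Gene table -> cross-tabulation

def _validate_gene_table(gene_table: pd.DataFrame) -> None:
    required = {"coding_class", "genome_hit", "three_genotypes",
                "srna_similarity", "te_flag", "de_flag", "exclusivity"}
    missing = required - set(gene_table.columns)
    if missing:
        raise ValueError(f"gene table lacks columns: {sorted(missing)}")
    if gene_table[sorted(required)].isna().any().any():
        raise ValueError("gene table contains missing values")
    bad = set(gene_table["coding_class"]) - {"protein-coding", "lncRNA",
                                             "unclassified"}
    if bad:
        raise ValueError(f"unknown coding classes: {sorted(bad)}")


def crosstab_counts_from_gene_table(gene_table: pd.DataFrame) -> pd.DataFrame:
    """Count matrix (stratum, feature) x (not_de, de) over lncRNAs."""
    _validate_gene_table(gene_table)
    lnc = gene_table[gene_table["coding_class"] == "lncRNA"].copy()
    lnc["three_genotypes_and_genome_hit"] = (lnc["three_genotypes"]
                                             & lnc["genome_hit"])
    lnc["contains_transposons"] = lnc["te_flag"]
    strata = {
        "all": lnc,
        "meiocyte_exclusive": lnc[lnc["exclusivity"] == "meiocyte-exclusive"],
        "shared": lnc[lnc["exclusivity"] == "shared"],
    }
    rows = []
    for stratum, sub in strata.items():
        for feature in CROSSTAB_FEATURES:
            sel = sub[sub[feature]]
            rows.append({"stratum": stratum, "feature": feature,
                         "not_de": int((~sel["de_flag"]).sum()),
                         "de": int(sel["de_flag"].sum())})
        rows.append({"stratum": stratum, "feature": "total",
                     "not_de": int((~sub["de_flag"]).sum()),
                     "de": int(sub["de_flag"].sum())})
    return pd.DataFrame(rows)


def build_crosstab(counts: pd.DataFrame) -> pd.DataFrame:
    """Cross-tabulation with percentages from (stratum, feature) counts.

    ``counts`` has columns stratum, feature, not_de, de (a gene table
    can be converted with :func:`crosstab_counts_from_gene_table`).
    DE/not-DE percentages are relative to the lncRNAs carrying the
    feature; feature totals are relative to the stratum total.
    """
    df = counts.copy()
    df["total"] = df["not_de"] + df["de"]
    out = []
    for stratum, sub in df.groupby("stratum", sort=False):
        totals = sub[sub["feature"] == "total"]
        if len(totals) != 1:
            raise ValueError(f"stratum {stratum!r} needs exactly one total row")
        stratum_total = int(totals["total"].iloc[0])
        for _, row in sub.iterrows():
            total = int(row["total"])
            out.append({
                "stratum": stratum, "feature": row["feature"],
                "not_de": int(row["not_de"]),
                "not_de_pct": percentage(row["not_de"], total) if total else 0.0,
                "de": int(row["de"]),
                "de_pct": percentage(row["de"], total) if total else 0.0,
                "total": total,
                "total_pct": percentage(total, stratum_total)
                if stratum_total else 0.0,
            })
    return pd.DataFrame(out)


def crosstab_conservation_check(crosstab: pd.DataFrame) -> bool:
    """Exclusive + shared counts must reproduce the 'all' stratum, and
    not_de + de must equal total in every row."""
    if not ((crosstab["not_de"] + crosstab["de"]) == crosstab["total"]).all():
        return False
    pivot = crosstab.pivot(index="feature", columns="stratum", values="total")
    if {"all", "meiocyte_exclusive", "shared"} - set(pivot.columns):
        return True  # nothing to cross-check
    return bool((pivot["meiocyte_exclusive"] + pivot["shared"]
                 == pivot["all"]).all())


# ---------------------------------------------------------------------------
# DEG coding-class tree

def deg_breakdown(total_genes: int, deg: int, noncoding_de: int,
                  lncrna_de: int) -> pd.DataFrame:
    """DEG tree: DEG share of all genes, coding/non-coding split of the
    DEGs, lncRNA/unclassified split of the non-coding DEGs, and the
    final three-way split referenced to the DEG total.
    """
    if total_genes <= 0:
        raise ValueError("empty gene table")
    if not 0 <= noncoding_de <= deg <= total_genes:
        raise ValueError("inconsistent DEG counts")
    if not 0 <= lncrna_de <= noncoding_de:
        raise ValueError("lncRNA DEGs exceed non-coding DEGs")
    coding_de = deg - noncoding_de
    unclassified_de = noncoding_de - lncrna_de
    rows = [
        ("deg", deg, total_genes),
        ("coding_de", coding_de, deg),
        ("noncoding_de", noncoding_de, deg),
        ("lncrna_de", lncrna_de, noncoding_de),
        ("unclassified_de", unclassified_de, noncoding_de),
        ("lncrna_de_of_deg", lncrna_de, deg),
        ("unclassified_de_of_deg", unclassified_de, deg),
        ("coding_de_of_deg", coding_de, deg),
    ]
    return pd.DataFrame(
        [{"quantity": q, "count": n, "reference": d,
          "percent": percentage(n, d)} for q, n, d in rows]
    ).set_index("quantity")


def deg_breakdown_from_gene_table(gene_table: pd.DataFrame) -> pd.DataFrame:
    _validate_gene_table(gene_table)
    de = gene_table[gene_table["de_flag"]]
    noncoding = de[de["coding_class"] != "protein-coding"]
    return deg_breakdown(len(gene_table), len(de), len(noncoding),
                         int((noncoding["coding_class"] == "lncRNA").sum()))


# ---------------------------------------------------------------------------
# Proportion comparisons

def compare_proportions_report(comparisons: pd.DataFrame,
                               alpha: float = 0.01) -> pd.DataFrame:
    """Two-proportion tests, one output row per comparison.

    ``comparisons`` columns: name, x1, n1, x2, n2.  Adds the two
    percentages, the pooled z-test p-value and a significance flag.
    """
    rows = []
    for _, row in comparisons.iterrows():
        p = proportion_test(int(row["x1"]), int(row["n1"]),
                            int(row["x2"]), int(row["n2"]))
        rows.append({"name": row["name"],
                     "pct1": percentage(row["x1"], row["n1"]),
                     "pct2": percentage(row["x2"], row["n2"]),
                     "p_value": p, "significant": p < alpha})
    return pd.DataFrame(rows).set_index("name")
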