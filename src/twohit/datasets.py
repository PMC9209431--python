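"""Reference numbers bundled with the package.

``reference_funnel`` returns the germline filtering funnel of the familial
cholangiocarcinoma exome analysis this pipeline models: joint high-quality
variant counts across the eight siblings, the subset shared by all four
affected siblings, the protein-altering subset with its per-class breakdown,
and the final rare-variant tally with its distinct-gene collapse.  The
per-stage arithmetic (class sums and stage-to-stage percentages) is computed
by :func:`funnel_identities`, not stored.
"""

from __future__ import annotations

__all__ = ["reference_funnel", "funnel_identities"]


def reference_funnel() -> dict:
    """The reference familial-CCA exome funnel counts (eight-sibling sibship,
    four affected)."""
    return {
        "combined_high_quality": {"snv": 46_133, "indel": 5_603},
        "shared_in_all_affected": {"total": 22_969},
        "protein_altering": {
            "total": 7_897,
            "snv_classes": {
                "nonsynonymous": 6_610,
                "splice_site": 656,
                "stop_codon": 75,
            },
            "indel_classes": {
                "inframe": 203,
                "frameshift": 191,
                "splice_site": 162,
            },
        },
        "rare_in_population": {"snv": 43, "indel": 157, "genes": 148},
    }


def funnel_identities(funnel: dict | None = None) -> dict:
    """Arithmetic identities of a funnel: class sums and stage percentages.

    Returns the sum of the per-class protein-altering counts, the shared and
    protein-altering fractions as percentages of the preceding stage, and the
    final variant total.
    """
    f = funnel or reference_funnel()
    combined = f["combined_high_quality"]["snv"] + f["combined_high_quality"]["indel"]
    shared = f["shared_in_all_affected"]["total"]
    impact = f["protein_altering"]
    class_sum = sum(impact["snv_classes"].values()) + sum(
        impact["indel_classes"].values()
    )
    final = f["rare_in_population"]
    return {
        "combined_total": combined,
        "protein_altering_class_sum": class_sum,
        "protein_altering_total": impact["total"],
        "shared_fraction_pct": 100.0 * shared / combined,
        "protein_altering_fraction_pct": 100.0 * impact["total"] / shared,
        "final_variant_total": final["snv"] + final["indel"],
        "final_gene_count": final["genes"],
    }
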