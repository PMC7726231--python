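"""Printed reference tables from the raptor-silencing trophoblast microarray study.

These are the published numbers the package's calibration and reporting
stages take as input: the KEGG pathway enrichment tables (per-pathway counts
of differentially regulated genes, catalog set sizes, and directional
z-scores), the headline DEG partition (739 genes: 252 up, 487 down between
scramble-siRNA and raptor-siRNA primary human trophoblast cells; raw array
data deposited as GEO accession GSE40878), and the clinical summary of the
AGA/IUGR placenta cohort used in the protein-expression stage.

The pathway tables print r (genes from the DEG list annotated to the
pathway), n (catalog pathway size) and z, but not the background universe
size N — :func:`degpath.enrichment.calibrate_background` recovers it from
these rows.
"""

from __future__ import annotations

__all__ = [
    "N_DEG_TOTAL", "N_DEG_UP", "N_DEG_DOWN",
    "PATHWAYS_DOWN", "PATHWAYS_UP",
    "calibration_rows",
    "CLINICAL_AGA", "CLINICAL_IUGR",
    "down_percent", "percent_reduction",
]

# Headline DEG partition (raw t-test p < 0.05, 4 vs 4 arrays).
N_DEG_UP = 252
N_DEG_DOWN = 487
N_DEG_TOTAL = N_DEG_UP + N_DEG_DOWN  # 739

# Down-regulated KEGG pathways:
# (pathway, diff_regulated, r_up, r_down, catalog_size, z_down)
PATHWAYS_DOWN: tuple[tuple[str, int, int, int, int, float], ...] = (
    ("Amino sugar and nucleotide sugar metabolism", 4, 0, 4, 47, 2.65),
    ("Biosynthesis of unsaturated fatty acids", 3, 0, 3, 21, 3.47),
    ("Butirosin and neomycin biosynthesis", 1, 0, 1, 5, 2.51),
    ("Cardiac muscle contraction", 5, 0, 5, 73, 2.4),
    ("Cysteine and methionine metabolism", 3, 0, 3, 35, 2.31),
    ("Glutathione metabolism", 4, 0, 4, 50, 2.5),
    ("Glycolysis/Gluconeogenesis", 5, 0, 5, 65, 2.7),
    ("Glycosphingolipid biosynthesis - ganglio series", 2, 0, 2, 15, 2.69),
    ("Glyoxylate and dicarboxylate metabolism", 4, 1, 3, 18, 3.86),
    ("Metabolic pathways", 54, 5, 49, 1080, 4.76),
    ("Oxidative phosphorylation", 11, 0, 11, 119, 4.76),
    ("Propanoate metabolism", 3, 0, 3, 32, 2.5),
    ("Purine metabolism", 10, 2, 8, 157, 2.11),
    ("Pyrimidine metabolism", 7, 1, 6, 95, 2.4),
    ("Ribosome", 19, 1, 18, 88, 10.87),
    ("RNA polymerase", 3, 0, 3, 28, 2.79),
    ("Vitamin B6 metabolism", 1, 0, 1, 5, 2.51),
)

# Up-regulated KEGG pathways:
# (pathway, diff_regulated, r_up, r_down, catalog_size, z_up)
PATHWAYS_UP: tuple[tuple[str, int, int, int, int, float], ...] = (
    ("alpha-Linolenic acid metabolism", 1, 1, 0, 17, 2.38),
    ("Antigen processing and presentation", 3, 2, 1, 66, 2.08),
    ("Arachidonic acid metabolism", 2, 2, 0, 55, 2.4),
    ("Cell adhesion molecules (CAMs)", 5, 4, 1, 127, 3.05),
    ("Complement and coagulation cascades", 3, 3, 0, 68, 3.4),
    ("Graft-vs.-host disease", 4, 3, 1, 35, 5.23),
    ("Intestinal immune network for IgA production", 4, 3, 1, 44, 4.55),
    ("Neuroactive ligand-receptor interaction", 9, 6, 3, 312, 2.34),
    ("Other glycan degradation", 1, 1, 0, 17, 2.38),
    ("Primary immunodeficiency", 2, 2, 0, 35, 3.31),
    ("Renin-angiotensin system", 1, 1, 0, 17, 2.38),
    ("Retinol metabolism", 3, 2, 1, 51, 2.55),
    ("RNA degradation", 5, 2, 3, 69, 2.0),
    ("Staphylococcus aureus infection", 5, 2, 3, 51, 2.55),
    ("Vascular smooth muscle contraction", 5, 5, 0, 123, 4.16),
)


def calibration_rows(direction: str) -> list[tuple[int, int, float]]:
    """(r, n, z_printed) rows for :func:`~degpath.enrichment.calibrate_background`.

    ``direction`` is ``"down"`` (R = 487) or ``"up"`` (R = 252); r is the
    directional count and n the printed catalog set size.
    """
    if direction == "down":
        return [(rd, size, z) for _, _, _, rd, size, z in PATHWAYS_DOWN]
    if direction == "up":
        return [(ru, size, z) for _, _, ru, _, size, z in PATHWAYS_UP]
    raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")


# Clinical summary of the placenta cohort (mean, SEM, n).
CLINICAL_AGA = {
    "n": 19,
    "birth_weight_g": (2493.0, 236.0),
    "placental_weight_g": (566.0, 42.0),
}
CLINICAL_IUGR = {
    "n": 25,
    "birth_weight_g": (1804.0, 110.0),
    "placental_weight_g": (394.0, 18.4),
}


def down_percent(n_down: int = N_DEG_DOWN, n_total: int = N_DEG_TOTAL) -> float:
    """Percentage of DEGs that are down-regulated (487/739 -> 65.9, i.e. 66%)."""
    return 100.0 * n_down / n_total


def percent_reduction(control_mean: float, case_mean: float) -> float:
    """Percent decrease of a case-group mean relative to the control mean."""
    return 100.0 * (control_mean - case_mean) / control_mean
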