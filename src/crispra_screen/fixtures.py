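"""Packaged fixtures: the validated interaction table, the benchmark
mini-library design, a toy protein family and a toy expression matrix.

The interaction table lists the 22 ligand-receptor pairs validated in the
screening study (18 from the single-pass TM1 library, 4 from the multi-pass
TM2+ library, across 12 ligand screens), with provenance (direct screen hit
vs phylogenetic homology analysis) and validation assays.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .interactome import InteractionEdge
from .simulate import ScreenDesign

__all__ = [
    "table1_edges",
    "table1_frame",
    "mini_library_design",
    "toy_protein_family",
    "toy_expression_matrix",
    "make_fixtures",
]

# ligand (screen), receptor (hit), library, source, assays
_TABLE1 = [
    ("GAS1", "PTPRA", "TM1", "Screen", ("SPR", "CSS")),
    ("OMG", "PTPRD", "TM1", "PHA", ("SPR",)),
    ("OMG", "PTPRF", "TM1", "PHA", ("SPR",)),
    ("OMG", "PTPRS", "TM1", "PHA", ("SPR",)),
    ("OMG", "PTPRU", "TM1", "Screen", ("SPR",)),
    ("OSTN", "PTPRU", "TM1", "Screen", ("SPR",)),
    ("MK", "RNF167", "TM1", "Screen", ("SPR",)),
    ("PTN", "RNF167", "TM1", "Screen", ("SPR",)),
    ("PTN", "ROR1", "TM1", "Screen", ("SPR",)),
    ("PTN", "MFRP", "TM1", "Screen", ("SPR",)),
    ("SMOC1", "SMOC1", "TM1", "PHA", ("SPR",)),
    ("SMOC1", "SMOC2", "TM1", "Screen", ("SPR",)),
    ("TAFA2", "KIR3DL1", "TM1", "Screen", ("SPR", "CSS")),
    ("TAFA2", "KIR3DL2", "TM1", "PHA", ("SPR", "CSS")),
    ("TAFA2", "KIR3DL3", "TM1", "Screen", ("CSS",)),
    ("TAFA2", "KIR2DL5A", "TM1", "PHA", ("CSS",)),
    ("TAFA2", "RNF167", "TM1", "Screen", ("SPR",)),
    ("TAFA5", "RNF167", "TM1", "Screen", ("SPR",)),
    ("LY6H", "CD36", "TM2+", "Screen", ("CSS",)),
    ("NRN1", "CD36", "TM2+", "Screen", ("CSS",)),
    ("SCRG1", "CD36", "TM2+", "Screen", ("CSS",)),
    ("VWC2L", "CD36", "TM2+", "Screen", ("CSS",)),
]

# the 10 well-characterized receptors of the benchmark mini-library
MINI_LIBRARY_GENES = (
    "IL2RA", "CD5", "CD272", "CD2", "CD28",
    "CD80", "CD45", "IL6ST", "CD276", "CD47",
)


def table1_edges() -> list[InteractionEdge]:
    return [
        InteractionEdge(ligand=l, receptor=r, library=lib, source=src, assays=a)
        for l, r, lib, src, a in _TABLE1
    ]


def table1_frame() -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "ligand": l,
                "receptor": r,
                "library": lib,
                "source": src,
                "assays": ",".join(a),
            }
            for l, r, lib, src, a in _TABLE1
        ]
    )


def mini_library_design(
    true_receptors: dict[str, float] | None = None,
) -> ScreenDesign:
    """The 10-target / 100-guide benchmark mini-library with 100 matched
    controls.  By default IL2RA (CD25) is the strength-1 true receptor,
    mirroring the IL-2 proof-of-concept screen."""
    if true_receptors is None:
        true_receptors = {"IL2RA": 1.0}
    return ScreenDesign(
        gene_ids=MINI_LIBRARY_GENES,
        guides_per_gene=10,
        n_controls=100,
        true_receptors=true_receptors,
        library_label="mini",
    )


def toy_protein_family() -> dict[str, str]:
    """Small synthetic protein family with graded divergence, for alignment
    and tree exercises (synthetic sequences, not database entries)."""
    base = "MKTLLVAAGLLACSQAWDNKFETDVKGTWEELRSLSNPQHVRPMQACGVND"
    return {
        "REC1": base,
        "REC2": base[:40] + "YHIMKACGAND",
        "REC3": base[:25] + "PGSDVKATWQELRGMSNAQHVRPIQ",
        "REC4": "MSPARRLLPLLLLLACSAHAWNNQFETEVRGSWDDLRHLANPQWVRPVE",
        "OUT1": "MAFWKSLVTTALFLGTSESSIIQRTPGENVTFSCHATGNPIPNVTWYKD",
    }


def toy_expression_matrix(seed: int = 7) -> pd.DataFrame:
    """Synthetic genes x tissues expression matrix with two co-expressed
    blocks, emulating normalized transcript abundance."""
    rng = np.random.default_rng(seed)
    tissues = [
        "brain", "cerebellum", "spinal_cord", "heart", "muscle",
        "liver", "kidney", "lung", "spleen", "blood",
    ]
    brain_profile = np.array([9, 8, 7, 1, 1, 0.5, 0.5, 1, 1, 0.5])
    immune_profile = np.array([0.5, 0.5, 1, 1, 1, 2, 1, 3, 8, 9])
    rows = {}
    for g in ("LIG_A", "REC_A", "LIG_B"):
        rows[g] = np.abs(brain_profile + rng.normal(0, 0.3, 10))
    for g in ("LIG_C", "REC_C", "REC_D"):
        rows[g] = np.abs(immune_profile + rng.normal(0, 0.3, 10))
    return pd.DataFrame(rows, index=tissues).T


def make_fixtures(output_dir) -> dict[str, Path]:
    """Write all packaged fixtures to ``output_dir``; reruns overwrite
    identically."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    paths["interactions"] = out / "validated_interactions.tsv"
    table1_frame().to_csv(paths["interactions"], sep="\t", index=False)

    design = mini_library_design()
    rows = []
    for gene in design.gene_ids:
        for k in range(design.guides_per_gene):
            rows.append((f"{gene}_sg{k + 1}", gene, "gene"))
    for k in range(design.n_controls):
        rows.append((f"CTRL_sg{k + 1}", "control", "safe"))
    paths["mini_library"] = out / "mini_library.tsv"
    pd.DataFrame(rows, columns=["guide_id", "gene_id", "category"]).to_csv(
        paths["mini_library"], sep="\t", index=False
    )

    paths["family_fasta"] = out / "toy_family.fasta"
    with open(paths["family_fasta"], "w") as fh:
        for name, seq in toy_protein_family().items():
            fh.write(f">{name} synthetic\n{seq}\n")

    paths["expression"] = out / "toy_expression.tsv"
    toy_expression_matrix().to_csv(paths["expression"], sep="\t")
    return paths
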