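"""Plain-text (TSV) readers and writers for every pipeline artifact.

All tables are tab-separated with a header row.  Genotypes are an
individuals x markers table of dosages {0,1,2}; kinship matrices are
labelled square tables; eQTL tables carry the six record fields.  A
minimal VCF export of genotypes is provided for interoperability, using
a fixed cM -> bp scale for positions.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from hseqtl.exprqc import ExpressionMatrix
from hseqtl.markers import MarkerMap
from hseqtl.popsim import CM_TO_BP, FounderPanel


def write_marker_map(mm: MarkerMap, path) -> None:
    mm.to_frame().to_csv(path, sep="\t", index=False)


def read_marker_map(path) -> MarkerMap:
    return MarkerMap.from_frame(pd.read_csv(path, sep="\t", dtype={"chromosome": str}))


def write_genotypes(dosages: np.ndarray, individual_ids, marker_ids, path) -> None:
    pd.DataFrame(dosages, index=individual_ids, columns=marker_ids).to_csv(
        path, sep="\t", index_label="individual"
    )


def read_genotypes(path) -> tuple[np.ndarray, list[str], list[str]]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(np.int8), df.index.astype(str).tolist(), df.columns.astype(str).tolist()


def write_matrix(M: np.ndarray, labels, path) -> None:
    pd.DataFrame(M, index=labels, columns=labels).to_csv(path, sep="\t", index_label="id")


def read_matrix(path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(float), df.index.astype(str).tolist()


def write_expression(expr: ExpressionMatrix, prefix: Path) -> None:
    prefix = Path(prefix)
    pd.DataFrame(expr.values, index=expr.sample_ids, columns=expr.probe_ids).to_csv(
        prefix.with_suffix(".expr.tsv"), sep="\t", index_label="sample"
    )
    expr.probes.to_csv(prefix.with_suffix(".probes.tsv"), sep="\t", index=False)
    if expr.detection_pvals is not None:
        pd.DataFrame(expr.detection_pvals, index=expr.sample_ids, columns=expr.probe_ids).to_csv(
            prefix.with_suffix(".detection.tsv"), sep="\t", index_label="sample"
        )


def read_expression(prefix: Path) -> ExpressionMatrix:
    prefix = Path(prefix)
    vals = pd.read_csv(prefix.with_suffix(".expr.tsv"), sep="\t", index_col=0)
    probes = pd.read_csv(prefix.with_suffix(".probes.tsv"), sep="\t", dtype={"chromosome": str})
    det_path = prefix.with_suffix(".detection.tsv")
    det = pd.read_csv(det_path, sep="\t", index_col=0).to_numpy(float) if det_path.exists() else None
    return ExpressionMatrix(
        values=vals.to_numpy(float),
        sample_ids=vals.index.astype(str).tolist(),
        probes=probes,
        detection_pvals=det,
    )


def write_eqtl_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_eqtl_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_vcf(
    dosages: np.ndarray,
    individual_ids,
    marker_map: MarkerMap,
    founder_panel: FounderPanel | None,
    path,
) -> None:
    """Minimal diploid-GT VCF export of the dosage matrix.

    One contig per chromosome; positions in bp on the fixed cM -> bp
    scale.  Dosage counts the ALT allele; phase is not represented.
    """
    gts = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=hseqtl\n")
        for c in marker_map.chromosomes:
            length = int(marker_map.chrom_length(c) * CM_TO_BP) + 1
            fh.write(f"##contig=<ID={c},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(map(str, individual_ids)) + "\n")
        for j, mid in enumerate(marker_map.marker_ids):
            pos = int(marker_map.pos_cM[j] * CM_TO_BP) + 1
            row = "\t".join(gts[int(d)] for d in dosages[:, j])
            fh.write(f"{marker_map.chrom[j]}\t{pos}\t{mid}\tA\tT\t.\tPASS\t.\tGT\t{row}\n")
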