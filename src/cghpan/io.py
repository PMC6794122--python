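"""Plain-text readers and writers for the pipeline's file formats.

Tab-separated tables throughout; MLST sequences as multi-FASTA (one record
per strain) via Biopython. Control probes are marked ``CONTROL`` in the
probe map's locus_tag column.
"""

from __future__ import annotations

import json

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .matrices import PresenceAbsenceMatrix, ProbeSignalMatrix, validate_annotations

CONTROL_TAG = "CONTROL"


def write_probe_matrix(matrix: ProbeSignalMatrix, path) -> None:
    matrix.values.rename_axis("probe_id").to_csv(path, sep="\t")


def write_probe_map(matrix: ProbeSignalMatrix, path) -> None:
    rows = [
        (pid, matrix.probe_to_gene.get(pid, CONTROL_TAG))
        for pid in matrix.values.index
    ]
    pd.DataFrame(rows, columns=["probe_id", "locus_tag"]).to_csv(
        path, sep="\t", index=False
    )


def read_probe_signals(probes_path, map_path) -> ProbeSignalMatrix:
    values = pd.read_csv(probes_path, sep="\t", index_col=0)
    pmap = pd.read_csv(map_path, sep="\t", index_col=0)["locus_tag"]
    controls = frozenset(pmap.index[pmap == CONTROL_TAG])
    probe_to_gene = pmap[pmap != CONTROL_TAG]
    return ProbeSignalMatrix(values, probe_to_gene, controls)


def write_annotations(annotations: pd.DataFrame, path) -> None:
    annotations.rename_axis("locus_tag").to_csv(path, sep="\t")


def read_annotations(path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t", index_col="locus_tag")
    return validate_annotations(ann)


def write_pa_matrix(pa: PresenceAbsenceMatrix, path) -> None:
    pa.values.astype(int).rename_axis("locus_tag").to_csv(path, sep="\t")


def read_pa_matrix(path) -> PresenceAbsenceMatrix:
    values = pd.read_csv(path, sep="\t", index_col=0).astype(bool)
    return PresenceAbsenceMatrix(values)


def write_mlst_fasta(seqs: dict[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in seqs.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_mlst_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_cutoff_report(result, path) -> None:
    """JSON report of a cutoff optimization (cutoff, pooled FDR/FNR,
    per-strain FDR table)."""
    with open(path, "w") as fh:
        json.dump(result.as_dict(), fh, indent=2, allow_nan=True)


def write_matrix_tsv(df: pd.DataFrame, path, index_name: str = "strain") -> None:
    df.rename_axis(index_name).to_csv(path, sep="\t")
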