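"""TSV / FASTA round-tripping for every table the pipeline exchanges.

All tables are UTF-8 tab-separated with '#'-prefixed header comment lines
(used for provenance: tool version, seed, parameters); data rows follow a
single header row. read(write(x)) == x for every format defined here.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .compare import OrthologMap
from .containers import (
    CountMatrix,
    EchinodevError,
    ModeMap,
    PresenceMatrix,
    ProteinSet,
    TimeCourseMatrix,
)

__all__ = [
    "provenance_lines",
    "write_table",
    "read_table",
    "write_count_matrix",
    "read_count_matrix",
    "write_timecourse",
    "read_timecourse",
    "write_mode_map",
    "read_mode_map",
    "write_presence",
    "read_presence",
    "write_ortholog_map",
    "read_ortholog_map",
    "write_gene_list",
    "read_gene_list",
    "write_fasta",
    "read_fasta",
    "read_config",
]


def provenance_lines(**params) -> list[str]:
    lines = [f"# echinodev {__version__}"]
    for key, value in params.items():
        lines.append(f"# {key}={value}")
    return lines


def write_table(df: pd.DataFrame, path, index_label: str | None = None, **params) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for line in provenance_lines(**params):
            fh.write(line + "\n")
        if index_label is None:
            df.to_csv(fh, sep="\t", index=False)
        else:
            df.to_csv(fh, sep="\t", index_label=index_label)


def read_table(path, index_col: int | None = 0, required: tuple[str, ...] = ()) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise EchinodevError(f"no such file: {path}")
    try:
        df = pd.read_csv(path, sep="\t", comment="#", index_col=index_col)
    except Exception as exc:  # surface file + cause
        raise EchinodevError(f"cannot parse {path}: {exc}") from exc
    missing = set(required) - set(df.columns)
    if missing:
        raise EchinodevError(f"{path}: missing columns {sorted(missing)}")
    return df


def write_count_matrix(m: CountMatrix, counts_path, meta_path, **params) -> None:
    write_table(m.counts, counts_path, index_label="ec", **params)
    write_table(m.sample_meta, meta_path, index_label="sample", **params)


def read_count_matrix(counts_path, meta_path) -> CountMatrix:
    counts = read_table(counts_path).astype(int)
    meta = read_table(meta_path, required=("hpf", "included"))
    meta["included"] = meta["included"].astype(bool)
    return CountMatrix(counts=counts, sample_meta=meta)


def write_timecourse(t: TimeCourseMatrix, path, **params) -> None:
    write_table(t.values, path, index_label="ec", unit=t.unit, **params)


def read_timecourse(path, unit: str | None = None) -> TimeCourseMatrix:
    if unit is None:
        unit = "rpkm"
        with Path(path).open(encoding="utf-8") as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                if line.startswith("# unit="):
                    unit = line.split("=", 1)[1].strip()
    df = read_table(path)
    df.columns = [float(c) for c in df.columns]
    return TimeCourseMatrix(values=df, unit=unit)


def write_mode_map(mm: ModeMap, path, extra: pd.DataFrame | None = None, **params) -> None:
    df = pd.DataFrame({"mode": mm.labels})
    if extra is not None:
        df = df.join(extra)
    write_table(df, path, index_label="gene", flat_eps=mm.flat_eps, **params)


def read_mode_map(path) -> ModeMap:
    df = read_table(path, required=("mode",))
    flat_eps = 0.05
    with Path(path).open(encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if line.startswith("# flat_eps="):
                flat_eps = float(line.split("=", 1)[1])
    return ModeMap(labels=df["mode"].astype(str), flat_eps=flat_eps)


def write_presence(pm: PresenceMatrix, path, **params) -> None:
    write_table(pm.present.astype(int), path, index_label="gene", **params)


def read_presence(path) -> PresenceMatrix:
    df = read_table(path).astype(bool)
    return PresenceMatrix(present=df)


def write_ortholog_map(om: OrthologMap, path, **params) -> None:
    write_table(om.pairs, path, index_label=None, **params)


def read_ortholog_map(path) -> OrthologMap:
    df = read_table(path, index_col=None, required=("gene_a", "gene_b", "relation"))
    return OrthologMap(pairs=df)


def write_gene_list(genes, path) -> None:
    Path(path).write_text("\n".join(sorted(genes)) + "\n", encoding="utf-8")


def read_gene_list(path) -> set[str]:
    text = Path(path).read_text(encoding="utf-8")
    return {line.strip() for line in text.splitlines() if line.strip() and not line.startswith("#")}


def write_fasta(p: ProteinSet, path, wrap: int = 80) -> None:
    records = [SeqRecord(Seq(seq), id=sid, description="") for sid, seq in p.sequences.items()]
    with Path(path).open("w", encoding="utf-8") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=wrap)
        writer.write_file(records)


def read_fasta(path) -> ProteinSet:
    path = Path(path)
    if not path.exists():
        raise EchinodevError(f"no such file: {path}")
    sequences = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    if not sequences:
        raise EchinodevError(f"no sequences in {path}")
    return ProteinSet(sequences)


def read_config(path) -> dict:
    """YAML or JSON configuration file -> dict."""
    path = Path(path)
    if not path.exists():
        raise EchinodevError(f"no such config file: {path}")
    text = path.read_text(encoding="utf-8")
    if path.suffix == ".json":
        return json.loads(text)
    return yaml.safe_load(text)
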