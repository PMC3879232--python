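"""Readers and writers for the plain-text formats the pipeline consumes and
emits: expression TSV, BED6, RepeatMasker ``.out``, FASTA, alignment tables,
and YAML run manifests."""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

__all__ = [
    "read_expression_tsv",
    "write_expression_tsv",
    "read_genes_bed",
    "write_genes_bed",
    "read_repeats_bed",
    "write_repeats_bed",
    "read_repeatmasker_out",
    "write_repeatmasker_out",
    "read_fasta",
    "write_fasta",
    "read_alignment_table",
    "write_alignment_table",
    "write_manifest",
    "repeat_class_of",
]

_CLASSES = ("LTR", "SINE", "LINE")


def repeat_class_of(family: str) -> str:
    """Map a RepeatMasker class/family string to {LTR, SINE, LINE, other}.

    SINE/Alu and all other SINE families collapse to SINE; anything not
    prefixed by a known retroelement class is "other".
    """
    head = family.split("/")[0].strip()
    return head if head in _CLASSES else "other"


def read_expression_tsv(path) -> pd.DataFrame:
    m = pd.read_csv(path, sep="\t", index_col=0)
    m.index = m.index.astype(str)
    return m


def write_expression_tsv(m: pd.DataFrame, path) -> None:
    m.to_csv(path, sep="\t", index_label="probe_id")


def write_genes_bed(genes: pd.DataFrame, path) -> None:
    """BED6: chrom, start, end, name, score(0), strand; 0-based half-open."""
    bed = pd.DataFrame(
        {
            "chrom": genes["chrom"],
            "start": genes["start"],
            "end": genes["end"],
            "name": genes["gene_id"],
            "score": 0,
            "strand": genes["strand"],
        }
    )
    bed.to_csv(path, sep="\t", header=False, index=False)


def read_genes_bed(path) -> pd.DataFrame:
    bed = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
        usecols=range(6),
    )
    return pd.DataFrame(
        {
            "gene_id": bed["name"].astype(str),
            "chrom": bed["chrom"].astype(str),
            "start": bed["start"].astype(int),
            "end": bed["end"].astype(int),
            "strand": bed["strand"].astype(str),
        }
    )


def write_repeats_bed(repeats: pd.DataFrame, path) -> None:
    """BED6 with the repeat class in the name field."""
    bed = pd.DataFrame(
        {
            "chrom": repeats["chrom"],
            "start": repeats["start"],
            "end": repeats["end"],
            "name": repeats["repeat_class"],
            "score": 0,
            "strand": ".",
        }
    )
    bed.to_csv(path, sep="\t", header=False, index=False)


def read_repeats_bed(path) -> pd.DataFrame:
    bed = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
        usecols=range(6),
    )
    return pd.DataFrame(
        {
            "chrom": bed["chrom"].astype(str),
            "start": bed["start"].astype(int),
            "end": bed["end"].astype(int),
            "repeat_class": bed["name"].astype(str).map(repeat_class_of),
        }
    )


_RM_HEADER = (
    "   SW  perc perc perc  query      position in query           matching"
    "       repeat              position in  repeat\n"
    "score  div. del. ins.  sequence    begin     end    (left)    repeat"
    "         class/family         begin  end (left)   ID\n\n"
)


def write_repeatmasker_out(repeats: pd.DataFrame, path) -> None:
    """Minimal RepeatMasker ``.out``: 1-based inclusive coordinates, class in
    the class/family column.  Intended for parser testing, not fidelity."""
    with open(path, "w") as fh:
        fh.write(_RM_HEADER)
        for i, r in enumerate(repeats.itertuples(index=False), start=1):
            fh.write(
                f"  225  10.0  0.0  0.0  {r.chrom} {r.start + 1} {r.end} (0) + "
                f"Synth-{i} {r.repeat_class}/Synthetic 1 {r.end - r.start} (0) {i}\n"
            )


def read_repeatmasker_out(path) -> pd.DataFrame:
    """Parse RepeatMasker ``.out``; converts 1-based inclusive to 0-based
    half-open and maps class/family strings onto {LTR, SINE, LINE, other}."""
    rows = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if len(parts) < 11 or not parts[0].isdigit():
                continue
            chrom, begin, end = parts[4], int(parts[5]), int(parts[6])
            family = parts[10]
            rows.append(
                {
                    "chrom": chrom,
                    "start": begin - 1,
                    "end": end,
                    "repeat_class": repeat_class_of(family),
                }
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "repeat_class"])


def write_fasta(sequences: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path) -> dict[str, str]:
    sequences: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                if name is not None:
                    sequences[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line)
    if name is not None:
        sequences[name] = "".join(chunks)
    return sequences


_ALN_COLS = [
    "chrom",
    "start",
    "end",
    "probe_id",
    "gene_id",
    "strand",
    "probe_length",
    "match_count",
]


def write_alignment_table(alignments: pd.DataFrame, path) -> None:
    alignments[_ALN_COLS].to_csv(path, sep="\t", index=False)


def read_alignment_table(path) -> pd.DataFrame:
    """Read a BED6-like alignment TSV with probe_length / match_count columns,
    or a PSL file (the matches column is used as the match count)."""
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("psLayout") or (
        first.split("\t")[0].isdigit() and len(first.split("\t")) >= 21
    ):
        return _read_psl(path)
    return pd.read_csv(path, sep="\t")


def _read_psl(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 21 or not parts[0].isdigit():
                continue
            rows.append(
                {
                    "chrom": parts[13],
                    "start": int(parts[15]),
                    "end": int(parts[16]),
                    "probe_id": parts[9],
                    "gene_id": parts[13],
                    "strand": parts[8],
                    "probe_length": int(parts[10]),
                    "match_count": int(parts[0]),
                }
            )
    return pd.DataFrame(rows, columns=_ALN_COLS)


def write_manifest(manifest: dict, path) -> None:
    Path(path).write_text(yaml.safe_dump(manifest, sort_keys=False))
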