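"""Minimal GFF3 gene-interval I/O.

Annotations are held internally as a DataFrame with 0-based half-open
``start``/``end``; GFF3 files use 1-based closed coordinates, converted at
the boundary.
"""

from __future__ import annotations

import pandas as pd

ANNOTATION_COLUMNS = ["genome", "chromosome", "start", "end", "strand", "gene_id"]


def write_gff3(annotations: pd.DataFrame, path, source: str = "oatcompass") -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write("##gff-version 3\n")
        for rec in annotations.sort_values(["chromosome", "start"]).itertuples(index=False):
            fh.write(
                "\t".join(
                    [
                        rec.chromosome,
                        source,
                        "gene",
                        str(rec.start + 1),  # to 1-based closed
                        str(rec.end),
                        ".",
                        rec.strand,
                        ".",
                        f"ID={rec.gene_id}",
                    ]
                )
                + "\n"
            )


def read_gff3(path, genome: str = "") -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != "gene":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
            )
            rows.append(
                {
                    "genome": genome,
                    "chromosome": f[0],
                    "start": int(f[3]) - 1,  # to 0-based half-open
                    "end": int(f[4]),
                    "strand": f[6],
                    "gene_id": attrs.get("ID", "."),
                }
            )
    return pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)
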