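"""Readers and writers for annotation and image formats.

GTF parsing is deliberately minimal: exon features grouped by
transcript_id, which is all the downstream operations consume.
"""

from __future__ import annotations

import re
from typing import Dict, List, Tuple

import numpy as np

from annotaudit.fiveprime import TranscriptModel

_GTF_ATTR = re.compile(r'(\w+) "([^"]*)"')


def read_gtf_models(path: str) -> List[TranscriptModel]:
    """Transcript models from the exon features of a GTF file."""
    exons: Dict[str, List[Tuple[int, int]]] = {}
    meta: Dict[str, Tuple[str, str, str]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9 or fields[2] != "exon":
                continue
            chrom, _, _, start, end, _, strand, _, attrs = fields[:9]
            attr = dict(_GTF_ATTR.findall(attrs))
            tid = attr.get("transcript_id")
            if tid is None:
                raise ValueError(f"exon without transcript_id: {line.strip()}")
            exons.setdefault(tid, []).append((int(start) - 1, int(end)))
            meta[tid] = (attr.get("gene_id", tid), chrom, strand)
    models = []
    for tid, ex in exons.items():
        gene_id, chrom, strand = meta[tid]
        models.append(TranscriptModel(tid, gene_id, chrom, strand, sorted(ex)))
    return models


def write_gtf_models(models: List[TranscriptModel], path: str) -> None:
    with open(path, "w") as fh:
        for m in models:
            for start, end in m.exons:
                attrs = f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}";'
                fh.write(
                    f"{m.chrom}\tannotaudit\texon\t{start + 1}\t{end}\t.\t"
                    f"{m.strand}\t.\t{attrs}\n"
                )


def read_bed12_models(path: str) -> List[TranscriptModel]:
    """Transcript models from a BED12 file (one transcript per line)."""
    models = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("track", "#")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ValueError("BED12 requires 12 columns")
            chrom, start, _end, name, _, strand = f[0], int(f[1]), int(f[2]), f[3], f[4], f[5]
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            exons = [(start + o, start + o + s) for o, s in zip(offsets, sizes)]
            models.append(TranscriptModel(name, name, chrom, strand, exons))
    return models


def write_tiff(plane: np.ndarray, path: str) -> None:
    import tifffile

    tifffile.imwrite(path, np.asarray(plane))


def read_tiff(path: str) -> np.ndarray:
    import tifffile

    return tifffile.imread(path)
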