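"""Plain-text readers and writers for the pipeline's exchange formats.

Conventions: PED/MAP use the PLINK text dialect (alleles 1/2, 0 missing;
MAP positions 1-based).  BED is 0-based half-open.  AGP 2.1 is 1-based
inclusive.  SexMap and interval TSVs carry a header comment declaring
their coordinate convention.  Readers report malformed lines with line
numbers.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .core import MISSING, GeneAnnotation, GenomeSpec, GenotypeData, SEXMAP_COLUMNS

_SEX_TO_PLINK = {"M": "1", "F": "2"}
_PLINK_TO_SEX = {"1": "M", "2": "F"}


# --------------------------------------------------------------------------
# PED / MAP


def write_ped_map(gd: GenotypeData, prefix) -> None:
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    with open(prefix.with_suffix(".map"), "w") as fh:
        for _, m in gd.markers.iterrows():
            fh.write(f"{m['chrom']}\t{m['id']}\t0\t{m['pos_bp']}\n")
    # dosage -> allele pair strings ('2' = alternate allele)
    allele_pairs = np.array(["0 0", "1 1", "1 2", "2 2"])
    with open(prefix.with_suffix(".ped"), "w") as fh:
        for i, s in gd.samples.iterrows():
            geno = allele_pairs[gd.genotypes[i] + 1]
            fh.write(
                "\t".join(
                    [
                        s["fid"],
                        s["iid"],
                        s["father"],
                        s["mother"],
                        _SEX_TO_PLINK.get(s["sex"], "0"),
                        "-9",
                    ]
                    + list(geno)
                )
                + "\n"
            )


def read_ped_map(prefix) -> GenotypeData:
    prefix = Path(prefix)
    markers = []
    with open(prefix.with_suffix(".map")) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if len(parts) != 4:
                raise ValueError(f"{prefix.with_suffix('.map')}:{ln}: expected 4 fields")
            chrom, mid, _, pos = parts
            markers.append((mid, chrom, int(pos)))
    markers = pd.DataFrame(markers, columns=["id", "chrom", "pos_bp"])

    dose = {("1", "1"): 0, ("1", "2"): 1, ("2", "1"): 1, ("2", "2"): 2}
    rows, genos = [], []
    with open(prefix.with_suffix(".ped")) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if len(parts) != 6 + 2 * len(markers):
                raise ValueError(
                    f"{prefix.with_suffix('.ped')}:{ln}: expected "
                    f"{6 + 2 * len(markers)} fields, got {len(parts)}"
                )
            fid, iid, fa, mo, sex, _ = parts[:6]
            rows.append((fid, iid, fa, mo, _PLINK_TO_SEX.get(sex, "0")))
            alleles = parts[6:]
            g = np.fromiter(
                (
                    dose.get((alleles[2 * j], alleles[2 * j + 1]), MISSING)
                    for j in range(len(markers))
                ),
                dtype=np.int8,
                count=len(markers),
            )
            genos.append(g)
    samples = pd.DataFrame(rows, columns=["fid", "iid", "father", "mother", "sex"])
    return GenotypeData(np.stack(genos), samples, markers)


# --------------------------------------------------------------------------
# pedigree, genome, genes


def write_pedigree_tsv(samples: pd.DataFrame, path) -> None:
    samples[["fid", "iid", "father", "mother", "sex"]].rename(
        columns={"fid": "family", "iid": "id"}
    ).to_csv(path, sep="\t", index=False)


def read_pedigree_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    need = {"family", "id", "father", "mother", "sex"}
    if not need <= set(df.columns):
        raise ValueError(f"{path}: pedigree TSV needs columns {sorted(need)}")
    if df["id"].duplicated().any():
        raise ValueError(f"{path}: duplicate individual ids")
    return df.rename(columns={"family": "fid", "id": "iid"})


def write_genome_tsv(genome: GenomeSpec, path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tlength_bp\tclass\n")
        for c in genome:
            fh.write(f"{c.name}\t{c.length_bp}\t{'macro' if c.is_macro else 'micro'}\n")


def read_genome_tsv(path) -> GenomeSpec:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    from .core import Chromosome

    return GenomeSpec(
        [
            Chromosome(r["chrom"], int(r["length_bp"]), r["class"] == "macro")
            for _, r in df.iterrows()
        ]
    )


def write_genes_bed(genes: GeneAnnotation, path) -> None:
    """BED4+score; coordinates 0-based half-open; score 1 = named gene."""
    with open(path, "w") as fh:
        for _, g in genes.df.iterrows():
            fh.write(
                f"{g['chrom']}\t{g['start_bp']}\t{g['end_bp']}\t{g['id']}\t"
                f"{1 if g['named'] else 0}\n"
            )


def read_genes_bed(path, genome: GenomeSpec | None = None) -> GeneAnnotation:
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: BED needs at least 3 fields")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if end <= start:
                raise ValueError(f"{path}:{ln}: BED end must be > start")
            name = parts[3] if len(parts) > 3 else f"gene_{ln}"
            named = (parts[4] != "0") if len(parts) > 4 else True
            rows.append((name, chrom, start, end, named))
    return GeneAnnotation(
        pd.DataFrame(rows, columns=GeneAnnotation.COLUMNS), genome
    )


# --------------------------------------------------------------------------
# SexMap / interval tables


def write_sexmap_tsv(sexmap: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write("# pos_bp: 1-based physical position; cM columns cumulative per chromosome\n")
        sexmap[SEXMAP_COLUMNS].to_csv(fh, sep="\t", index=False)


def read_sexmap_tsv(path) -> pd.DataFrame:
    from .core import validate_sexmap

    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
    return validate_sexmap(df)


def write_intervals_tsv(intervals: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write("# start_bp/end_bp: 0-based half-open 1 Mb windows\n")
        intervals.to_csv(fh, sep="\t", index=False)


def read_intervals_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})


def write_intervals_bed(intervals: pd.DataFrame, path, score_col: str = "diff") -> None:
    """Intervals as BED with the chosen heterochiasmy measure as score."""
    with open(path, "w") as fh:
        fh.write(f"# score column: {score_col}; coordinates 0-based half-open\n")
        for _, r in intervals.iterrows():
            score = r.get(score_col, float("nan"))
            fh.write(
                f"{r['chrom']}\t{int(r['start_bp'])}\t{int(r['end_bp'])}\t"
                f"{r['chrom']}:{int(r['start_bp'])}\t{score}\n"
            )


# --------------------------------------------------------------------------
# AGP 2.1


def write_agp(order: pd.DataFrame, object_name: str, path, gap: int = 100) -> None:
    """AGP 2.1 from a contig order table (columns contig, length_bp, orientation)."""
    with open(path, "w") as fh:
        fh.write("##agp-version\t2.1\n")
        beg = 1
        part = 1
        for i, r in order.iterrows():
            end = beg + int(r["length_bp"]) - 1
            fh.write(
                f"{object_name}\t{beg}\t{end}\t{part}\tW\t{r['contig']}\t1\t"
                f"{int(r['length_bp'])}\t{r['orientation']}\n"
            )
            part += 1
            beg = end + 1
            if i != order.index[-1]:
                fh.write(
                    f"{object_name}\t{beg}\t{beg + gap - 1}\t{part}\tN\t{gap}\t"
                    "scaffold\tyes\tmap\n"
                )
                part += 1
                beg += gap


def read_agp(path) -> pd.DataFrame:
    rows = []
    prev_end = 0
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9:
                raise ValueError(f"{path}:{ln}: AGP line needs 9 fields")
            beg, end = int(parts[1]), int(parts[2])
            if beg <= prev_end:
                raise ValueError(f"{path}:{ln}: object coordinates must increase")
            prev_end = end
            rows.append(
                {
                    "object": parts[0],
                    "object_beg": beg,
                    "object_end": end,
                    "part_number": int(parts[3]),
                    "component_type": parts[4],
                    "component_id": parts[5],
                    "orientation": parts[8] if parts[4] == "W" else None,
                }
            )
    return pd.DataFrame(rows)
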