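"""Reading and writing genotype, phenotype, and kinship files.

Genotypes load from VCF (biallelic SNV GT records, via cyvcf2), PLINK
.ped/.map text, or a wide TSV of dosages.  After loading, each marker
is oriented so the dosage counts the in-sample minor allele; the
orientation is recorded per marker.  Multi-allelic records pass
through flagged (n_alleles > 2) so QC can reject them.  Coordinates
keep the source file's 1-based convention.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, KinshipMatrix, MarkerInfo, check_phenotypes


def _orient_minor(dosage: np.ndarray, markers: list[MarkerInfo]) -> None:
    """Flip dosages in place so each column counts the in-sample minor allele."""
    for j, mk in enumerate(markers):
        col = dosage[:, j]
        called = ~np.isnan(col)
        if not called.any():
            continue
        freq = col[called].mean() / 2.0
        if freq > 0.5:
            dosage[:, j] = np.where(called, 2.0 - col, np.nan)
            mk.flipped = True
            mk.counted_allele = (mk.ref_allele if mk.counted_allele == mk.alt_allele
                                 else mk.alt_allele)


def read_genotypes(path: str | Path, format: str | None = None) -> GenotypeMatrix:
    """Load genotypes, inferring the format from the extension if unset."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        ext = path.suffix.lower()
        format = {".vcf": "vcf", ".ped": "plink-text", ".tsv": "tsv"}.get(ext)
        if format is None:
            raise ValueError(f"cannot infer genotype format from {path.name!r}")
    if format == "vcf":
        return read_vcf(path)
    if format == "plink-text":
        return read_plink_text(path)
    if format == "tsv":
        return read_wide_tsv(path)
    raise ValueError(f"unknown genotype format {format!r}")


# ---------------------------------------------------------------------------
# VCF


def read_vcf(path: str | Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    markers: list[MarkerInfo] = []
    cols = []
    seen = set()
    for var in vcf:
        vid = var.ID or f"{var.CHROM}:{var.POS}"
        if vid in seen:
            raise ValueError(f"duplicate marker id {vid!r} in {path}")
        seen.add(vid)
        alts = list(var.ALT)
        n_alleles = 1 + len(alts)
        dos = np.full(len(samples), np.nan)
        for i, g in enumerate(var.genotypes):
            alleles = [a for a in g[:-1] if a >= 0]
            if len(alleles) == 2:
                dos[i] = float(sum(a == 1 for a in alleles))  # first ALT dosage
        markers.append(MarkerInfo(
            id=vid, chrom=str(var.CHROM), pos=int(var.POS),
            ref_allele=var.REF, alt_allele=",".join(alts) if alts else ".",
            n_alleles=n_alleles,
            counted_allele=alts[0] if alts else var.REF,
        ))
        cols.append(dos)
    if not cols:
        raise ValueError(f"no variant records in {path}")
    dosage = np.column_stack(cols)
    _orient_minor(dosage, markers)
    return GenotypeMatrix(dosage, markers, samples)


def write_vcf(genotypes: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal GT-only VCF (uncompressed text).

    Dosages are emitted on the original REF/ALT orientation, undoing
    any minor-allele flip, so a write-read round trip is lossless.
    """
    lines = ["##fileformat=VCFv4.2",
             '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
             "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
             + "\t".join(genotypes.samples)]
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    for j, mk in enumerate(genotypes.markers):
        col = genotypes.dosage[:, j]
        if mk.flipped:
            col = np.where(np.isnan(col), np.nan, 2.0 - col)
        gts = ["./." if np.isnan(v) else gt_map[float(v)] for v in col]
        lines.append("\t".join([mk.chrom, str(mk.pos), mk.id, mk.ref_allele,
                                mk.alt_allele, ".", "PASS", ".", "GT"] + gts))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# PLINK .ped / .map text


def read_plink_text(ped_path: str | Path, map_path: str | Path | None = None) -> GenotypeMatrix:
    ped_path = Path(ped_path)
    map_path = Path(map_path) if map_path else ped_path.with_suffix(".map")
    markers: list[MarkerInfo] = []
    seen = set()
    for ln, line in enumerate(map_path.read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 4:
            raise ValueError(f"{map_path}:{ln}: expected 4 columns, got {len(parts)}")
        chrom, mid, _cm, pos = parts
        if mid in seen:
            raise ValueError(f"duplicate marker id {mid!r} in {map_path}")
        seen.add(mid)
        markers.append(MarkerInfo(id=mid, chrom=chrom, pos=int(pos),
                                  ref_allele="?", alt_allele="?"))
    m = len(markers)
    samples, rows = [], []
    allele_sets: list[set] = [set() for _ in range(m)]
    raw: list[list[tuple[str, str]]] = []
    for ln, line in enumerate(Path(ped_path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 6 + 2 * m:
            raise ValueError(f"{ped_path}:{ln}: expected {6 + 2 * m} columns, got {len(parts)}")
        samples.append(parts[1])
        pairs = [(parts[6 + 2 * j], parts[7 + 2 * j]) for j in range(m)]
        raw.append(pairs)
        for j, (a, b) in enumerate(pairs):
            allele_sets[j].update(x for x in (a, b) if x != "0")
    if len(set(samples)) != len(samples):
        raise ValueError(f"duplicate sample ids in {ped_path}")
    dosage = np.full((len(samples), m), np.nan)
    for j, mk in enumerate(markers):
        alleles = sorted(allele_sets[j])
        mk.n_alleles = max(len(alleles), 1)
        ref = alleles[0] if alleles else "?"
        alt = alleles[1] if len(alleles) > 1 else (alleles[0] if alleles else "?")
        mk.ref_allele, mk.alt_allele = ref, alt
        mk.counted_allele = alt
        for i, pairs in enumerate(raw):
            a, b = pairs[j]
            if a == "0" or b == "0":
                continue
            dosage[i, j] = float((a == alt) + (b == alt))
    _orient_minor(dosage, markers)
    return GenotypeMatrix(dosage, markers, samples)


def write_plink_text(genotypes: GenotypeMatrix, ped_path: str | Path) -> None:
    ped_path = Path(ped_path)
    map_lines = [f"{mk.chrom}\t{mk.id}\t0\t{mk.pos}" for mk in genotypes.markers]
    ped_path.with_suffix(".map").write_text("\n".join(map_lines) + "\n")
    ped_lines = []
    for i, sid in enumerate(genotypes.samples):
        fields = ["FAM", sid, "0", "0", "0", "-9"]
        for j, mk in enumerate(genotypes.markers):
            v = genotypes.dosage[i, j]
            counted = mk.counted_allele
            other = mk.ref_allele if counted != mk.ref_allele else mk.alt_allele
            if np.isnan(v):
                fields += ["0", "0"]
            elif v == 0:
                fields += [other, other]
            elif v == 1:
                fields += [other, counted]
            else:
                fields += [counted, counted]
        ped_lines.append(" ".join(fields))
    ped_path.write_text("\n".join(ped_lines) + "\n")


# ---------------------------------------------------------------------------
# Wide TSV (samples x markers minor-allele dosage)


def read_wide_tsv(path: str | Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    if df.columns.duplicated().any():
        dup = df.columns[df.columns.duplicated()].tolist()
        raise ValueError(f"duplicate marker ids in {path}: {dup}")
    dosage = df.to_numpy(dtype=float)
    markers = [MarkerInfo(id=c, chrom="0", pos=j + 1, ref_allele="A", alt_allele="B")
               for j, c in enumerate(df.columns)]
    _orient_minor(dosage, markers)
    return GenotypeMatrix(dosage, markers, [str(s) for s in df.index])


def write_wide_tsv(genotypes: GenotypeMatrix, path: str | Path) -> None:
    df = pd.DataFrame(genotypes.dosage, index=genotypes.samples,
                      columns=genotypes.marker_ids)
    out = df.map(lambda v: "NA" if np.isnan(v) else str(int(v)))
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Phenotypes and kinship


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    return check_phenotypes(pd.read_csv(path, sep="\t"))


def write_phenotypes(phen: pd.DataFrame, path: str | Path) -> None:
    out = check_phenotypes(phen).copy()
    out["adaoo"] = out["adaoo"].map(lambda v: f"{v:.6f}")
    out["edu_years"] = out["edu_years"].map(lambda v: f"{v:g}")
    out.to_csv(path, sep="\t", index=False)


def read_kinship(path: str | Path) -> KinshipMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise ValueError("kinship TSV must be square with matching row/column ids")
    return KinshipMatrix(df.to_numpy(dtype=float), [str(s) for s in df.columns])


def write_kinship(K: KinshipMatrix, path: str | Path) -> None:
    df = pd.DataFrame(K.values, index=K.samples, columns=K.samples)
    df.to_csv(path, sep="\t", float_format="%.10g")
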