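"""File I/O: VCF genotypes, TSV tables and catalogs, panels, manifests.

VCF is the genotype interchange format (GT fields, one sample column per
individual, positions 1-based); tables travel as TSV with a header and
round-trip losslessly at 12 significant digits; panels are
one-variant-per-line text with a JSON provenance sidecar.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from ._core import GenotypeMatrix
from .panel import Panel

logger = logging.getLogger(__name__)

__all__ = [
    "write_vcf",
    "read_genotypes_vcf",
    "write_table",
    "read_table",
    "write_dosage_tsv",
    "write_catalog_tsv",
    "read_catalog_tsv",
    "write_panel",
    "read_panel",
    "RunManifest",
]

FLOAT_FORMAT = "%.12g"


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_GT = {0: "0/0", 1: "0/1", 2: "1/1"}


def write_vcf(path, genotypes: GenotypeMatrix, catalog: pd.DataFrame) -> None:
    """Write simulated genotypes as an uncompressed VCF with GT fields."""
    path = Path(path)
    cat = catalog.set_index("variant_id")
    chroms = sorted(catalog["chromosome"].unique())
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=funcpanel\n")
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(genotypes.individual_ids)
            + "\n"
        )
        for j, vid in enumerate(genotypes.variant_ids):
            row = cat.loc[vid]
            gts = []
            for i in range(genotypes.n_individuals):
                if genotypes.missing is not None and genotypes.missing[i, j]:
                    gts.append("./.")
                else:
                    gts.append(_GT[int(round(genotypes.dosage[i, j]))])
            fh.write(
                f"{row['chromosome']}\t{row['position_bp']}\t{vid}\t"
                f"{row['ref_allele']}\t{row['alt_allele']}\t.\t.\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )


def read_genotypes_vcf(path) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Read a VCF into a dosage matrix and a catalog skeleton.

    Dosage is the count of non-reference alleles in GT; missing calls are
    flagged.  Multi-allelic records are preserved (alternate alleles
    comma-joined in the catalog) so the final biallelic filter can reject
    them downstream.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    dosages: list[np.ndarray] = []
    missing: list[np.ndarray] = []
    records = []
    for k, var in enumerate(vcf):
        gts = var.genotypes  # [[a, b, phased], ...]
        dose = np.zeros(len(samples))
        miss = np.zeros(len(samples), dtype=bool)
        for i, g in enumerate(gts):
            alleles = g[:-1]
            if any(a < 0 for a in alleles):
                miss[i] = True
            else:
                dose[i] = sum(1 for a in alleles if a > 0)
        vid = var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}"
        try:
            chrom = int(str(var.CHROM).removeprefix("chr"))
        except ValueError:
            chrom = str(var.CHROM)
        records.append(
            {
                "variant_id": vid,
                "chromosome": chrom,
                "position_bp": int(var.POS),
                "ref_allele": var.REF,
                "alt_allele": ",".join(var.ALT) if var.ALT else ".",
            }
        )
        dosages.append(dose)
        missing.append(miss)
    catalog = pd.DataFrame.from_records(records)
    if catalog["variant_id"].duplicated().any():
        dup = catalog.loc[catalog["variant_id"].duplicated(), "variant_id"].iloc[0]
        raise ValueError(f"duplicate variant id in VCF: {dup}")
    D = np.array(dosages).T if dosages else np.zeros((len(samples), 0))
    M = np.array(missing).T if missing else np.zeros((len(samples), 0), dtype=bool)
    gm = GenotypeMatrix(
        individual_ids=samples,
        variant_ids=catalog["variant_id"].tolist(),
        dosage=D,
        missing=M if M.any() else None,
    )
    catalog["maf"] = gm.maf()
    catalog["classes"] = [frozenset()] * len(catalog)
    return gm, catalog


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

def write_table(path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_table(path, schema: dict[str, type] | None = None) -> pd.DataFrame:
    """TSV with header; ``schema`` maps required columns to types."""
    df = pd.read_csv(path, sep="\t")
    if schema:
        missing = [c for c in schema if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing required columns {missing}")
        for col, typ in schema.items():
            try:
                df[col] = df[col].astype(typ)
            except (TypeError, ValueError) as exc:
                bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
                row = int(bad[0]) if len(bad) else -1
                raise ValueError(
                    f"{path}: column {col!r} row {row}: cannot convert to {typ.__name__}"
                ) from exc
        extra = [c for c in df.columns if c not in schema]
        if extra:
            logger.warning("%s: extra columns preserved: %s", path, extra)
    return df


def write_dosage_tsv(path, genotypes: GenotypeMatrix) -> None:
    df = pd.DataFrame(
        genotypes.dosage, index=genotypes.individual_ids, columns=genotypes.variant_ids
    )
    df.index.name = "individual_id"
    df.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)


def write_catalog_tsv(path, catalog: pd.DataFrame) -> None:
    """Catalog to TSV, one row per variant, classes semicolon-delimited."""
    out = catalog.copy()
    out["classes"] = [";".join(sorted(c)) for c in out["classes"]]
    out.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_catalog_tsv(path) -> pd.DataFrame:
    cat = pd.read_csv(path, sep="\t")
    cat["classes"] = [
        frozenset(c.split(";")) if isinstance(c, str) and c else frozenset()
        for c in cat["classes"]
    ]
    return cat


# ---------------------------------------------------------------------------
# panels
# ---------------------------------------------------------------------------

def write_panel(path, panel: Panel) -> None:
    """One variant id per line, plus a ``<path>.provenance.json`` sidecar."""
    path = Path(path)
    path.write_text("\n".join(panel.variant_ids) + ("\n" if panel.variant_ids else ""))
    sidecar = path.with_suffix(path.suffix + ".provenance.json")
    sidecar.write_text(json.dumps({"name": panel.name, **panel.provenance}, indent=2))


def read_panel(path, name: str | None = None) -> Panel:
    path = Path(path)
    ids = [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]
    provenance = {}
    sidecar = path.with_suffix(path.suffix + ".provenance.json")
    if sidecar.exists():
        provenance = json.loads(sidecar.read_text())
        name = name or provenance.pop("name", None)
    return Panel(name=name or path.stem, variant_ids=ids, provenance=provenance)


# ---------------------------------------------------------------------------
# manifest
# ---------------------------------------------------------------------------

def _digest(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclasses.dataclass
class RunManifest:
    """Reproducibility record emitted once per pipeline run."""

    command: str
    config: dict
    seeds: dict
    inputs: dict[str, str] = dataclasses.field(default_factory=dict)
    outputs: dict[str, str] = dataclasses.field(default_factory=dict)

    def add_input(self, path) -> None:
        self.inputs[str(path)] = _digest(Path(path))

    def add_output(self, path) -> None:
        self.outputs[str(path)] = _digest(Path(path))

    def write(self, path) -> None:
        from . import __version__

        Path(path).write_text(
            json.dumps(
                {
                    "command": self.command,
                    "version": __version__,
                    "config": self.config,
                    "seeds": self.seeds,
                    "inputs": self.inputs,
                    "outputs": self.outputs,
                },
                indent=2,
                default=str,
            )
        )
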