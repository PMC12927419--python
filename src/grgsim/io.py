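"""Readers and writers: phased VCF, plain matrix text, GRG-lite, .par/.phen.

The GRG-lite serialization is a versioned line-oriented text format (so
diffs are reviewable) that round-trips every field of a graph bit-exactly.
``.par`` and ``.phen`` follow the GCTA dialect: whitespace-delimited,
headerless by default.  Intermediate pipeline tables are tab-separated text
with a header.  All writers are deterministic given identical inputs.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .graph import FrequencyVector, GenotypeMatrix, Grg, GrgNode, Mutation

__all__ = [
    "read_vcf",
    "write_vcf",
    "read_matrix_text",
    "save_grg",
    "load_grg",
    "write_par",
    "read_par",
    "write_phen",
    "write_table",
    "GrgLiteError",
]

GRGLITE_VERSION = 1


class GrgLiteError(ValueError):
    """Raised on a malformed or version-incompatible GRG-lite file."""


# ---------------------------------------------------------------------------
# genotype input
# ---------------------------------------------------------------------------


def read_vcf(path: str | Path, samples: Sequence[str] | None = None) -> GenotypeMatrix:
    """Read phased diploid hard calls from a VCF (plain or gzip) file.

    Multiallelic records are split into one mutation per alt allele.  The
    haplotype order within an individual follows the GT field order, and the
    alt allele is coded 1.  Unphased ('/') or missing ('.') genotypes are
    rejected: the graph encodes hard calls only and no imputation policy is
    applied.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), samples=list(samples) if samples is not None else None)
    sample_names = list(vcf.samples)
    n = len(sample_names)
    columns: list[np.ndarray] = []
    mutations: list[Mutation] = []
    for var in vcf:
        gts = var.genotypes  # [[a0, a1, phased], ...]
        haps = np.empty(2 * n, dtype=np.int16)
        for i, gt in enumerate(gts):
            if len(gt) < 3:
                raise ValueError(
                    f"record at {var.CHROM}:{var.POS}, sample {sample_names[i]}: "
                    "diploid genotype required"
                )
            a0, a1, phased = gt[0], gt[1], gt[-1]
            if a0 < 0 or a1 < 0:
                raise ValueError(
                    f"missing genotype at {var.CHROM}:{var.POS} for sample "
                    f"{sample_names[i]} (hard calls required)"
                )
            if not phased:
                raise ValueError(
                    f"unphased genotype at {var.CHROM}:{var.POS} for sample "
                    f"{sample_names[i]} ('|' separator required)"
                )
            haps[2 * i] = a0
            haps[2 * i + 1] = a1
        for alt_index, alt in enumerate(var.ALT, start=1):
            mutations.append(
                Mutation(len(mutations), position=var.POS, ref_allele=var.REF, alt_allele=alt)
            )
            columns.append((haps == alt_index).astype(np.int8))
    values = (
        np.column_stack(columns) if columns else np.zeros((2 * n, 0), dtype=np.int8)
    )
    return GenotypeMatrix(values, mutations, sample_names)


def write_vcf(gm: GenotypeMatrix, path: str | Path, chrom: str = "1") -> None:
    """Write a minimal phased VCF (one biallelic record per mutation)."""
    path = Path(path)
    ids = gm.individual_ids
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(ids)
            + "\n"
        )
        for mut in gm.mutations:
            col = gm.values[:, mut.mutation_id]
            gts = "\t".join(
                f"{col[2 * i]}|{col[2 * i + 1]}" for i in range(len(ids))
            )
            fh.write(
                f"{chrom}\t{mut.position}\t.\t{mut.ref_allele}\t{mut.alt_allele}"
                f"\t.\t.\t.\tGT\t{gts}\n"
            )


def read_matrix_text(path: str | Path) -> GenotypeMatrix:
    """Read a plain 0/1 haploid matrix: one row per haplotype, whitespace-split."""
    values = np.loadtxt(str(path), dtype=np.int8, ndmin=2)
    return GenotypeMatrix(values)


# ---------------------------------------------------------------------------
# GRG-lite serialization
# ---------------------------------------------------------------------------


def _fmt_ids(ids: Sequence[int]) -> str:
    return ",".join(map(str, ids)) if ids else "-"


def _parse_ids(text: str, lineno: int) -> tuple[int, ...]:
    if text == "-":
        return ()
    try:
        return tuple(int(x) for x in text.split(","))
    except ValueError as exc:
        raise GrgLiteError(f"line {lineno}: bad id list {text!r}") from exc


def save_grg(grg: Grg, path: str | Path) -> None:
    """Serialize a graph to the GRG-lite text format (round-trip exact)."""
    with open(path, "w") as fh:
        fh.write(f"#grglite {GRGLITE_VERSION}\n")
        fh.write(
            f"H\t{grg.num_haploid_samples}\t{grg.num_nodes}\t{grg.num_mutations}\n"
        )
        fh.write("I\t" + "\t".join(grg.individual_ids) + "\n")
        for m in grg.mutations:
            freq = "." if m.frequency is None else repr(float(m.frequency))
            fh.write(
                f"M\t{m.mutation_id}\t{m.position}\t{m.ref_allele}\t{m.alt_allele}\t{freq}\n"
            )
        for nd in grg.nodes:
            fh.write(
                f"N\t{nd.node_id}\t{_fmt_ids(nd.children)}\t{_fmt_ids(nd.mutation_ids)}\n"
            )


def load_grg(path: str | Path) -> Grg:
    """Load a GRG-lite file; raises :class:`GrgLiteError` with a line number."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines or not lines[0].startswith("#grglite"):
        raise GrgLiteError("line 1: missing '#grglite <version>' header")
    try:
        version = int(lines[0].split()[1])
    except (IndexError, ValueError) as exc:
        raise GrgLiteError("line 1: unreadable version") from exc
    if version != GRGLITE_VERSION:
        raise GrgLiteError(
            f"line 1: format version {version} unsupported (expected {GRGLITE_VERSION})"
        )
    if len(lines) < 3:
        raise GrgLiteError(f"line {len(lines)}: truncated file (no H/I records)")
    h = lines[1].split("\t")
    if h[0] != "H" or len(h) != 4:
        raise GrgLiteError("line 2: expected 'H\\t<2N>\\t<nodes>\\t<mutations>'")
    two_n, n_nodes, n_muts = (int(x) for x in h[1:])
    i_rec = lines[2].split("\t")
    if i_rec[0] != "I":
        raise GrgLiteError("line 3: expected individual id record 'I'")
    individual_ids = i_rec[1:]
    mutations: list[Mutation] = []
    nodes: list[GrgNode] = []
    for lineno, line in enumerate(lines[3:], start=4):
        if not line:
            continue
        parts = line.split("\t")
        if parts[0] == "M":
            if len(parts) != 6:
                raise GrgLiteError(f"line {lineno}: mutation record needs 6 fields")
            freq = None if parts[5] == "." else float(parts[5])
            mutations.append(
                Mutation(int(parts[1]), int(parts[2]), parts[3], parts[4], freq)
            )
        elif parts[0] == "N":
            if len(parts) != 4:
                raise GrgLiteError(f"line {lineno}: node record needs 4 fields")
            nodes.append(
                GrgNode(
                    int(parts[1]),
                    _parse_ids(parts[2], lineno),
                    _parse_ids(parts[3], lineno),
                )
            )
        else:
            raise GrgLiteError(f"line {lineno}: unknown record type {parts[0]!r}")
    if len(nodes) != n_nodes or len(mutations) != n_muts:
        raise GrgLiteError(
            f"line {len(lines)}: truncated file — header promises {n_nodes} nodes / "
            f"{n_muts} mutations, found {len(nodes)} / {len(mutations)}"
        )
    return Grg(two_n, nodes, mutations, individual_ids)


# ---------------------------------------------------------------------------
# GCTA-style outputs
# ---------------------------------------------------------------------------


def write_par(
    effects,
    mutations: Sequence[Mutation],
    frequencies: FrequencyVector,
    path: str | Path,
    trait_id: int | None = None,
) -> None:
    """Write one trait's causal effects as a GCTA ``.par`` file.

    Headerless, whitespace(tab)-delimited columns in the order mutation_id,
    AlternateAllele, Position, RefAllele, Frequency, Effect — one line per
    causal mutation.  ``effects`` is an :class:`~grgsim.effects.EffectTable`;
    with multiple traits, ``trait_id`` selects which one to write.
    """
    df = effects.df
    traits = sorted(df["causal_mutation_id"].unique())
    if trait_id is None:
        if len(traits) > 1:
            raise ValueError(
                f"effect table holds traits {traits}; pass trait_id to select one"
            )
        trait_id = traits[0] if traits else 0
    sub = df[df["causal_mutation_id"] == trait_id]
    n_mut = len(mutations)
    with open(path, "w") as fh:
        for row in sub.itertuples(index=False):
            mid = int(row.mutation_id)
            if not (0 <= mid < n_mut):
                raise ValueError(f"effect refers to unknown mutation id {mid}")
            mut = mutations[mid]
            freq = float(frequencies.frequencies[mid])
            fh.write(
                f"{mid}\t{mut.alt_allele}\t{mut.position}\t{mut.ref_allele}"
                f"\t{freq!r}\t{float(row.effect_size)!r}\n"
            )


def read_par(path: str | Path, trait_id: int = 0) -> pd.DataFrame:
    """Parse a ``.par`` file back into (mutation_id, causal_mutation_id, effect_size)."""
    df = pd.read_csv(
        path,
        sep=r"\s+",
        header=None,
        float_precision="round_trip",
        names=[
            "mutation_id",
            "AlternateAllele",
            "Position",
            "RefAllele",
            "Frequency",
            "Effect",
        ],
    )
    return pd.DataFrame(
        {
            "mutation_id": df["mutation_id"].astype(int),
            "causal_mutation_id": trait_id,
            "effect_size": df["Effect"].astype(float),
        }
    )


def write_phen(
    pheno,
    path: str | Path,
    header: bool = False,
    id_style: str = "single",
    trait_id: int | None = None,
) -> None:
    """Write per-individual phenotypes as a GCTA ``.phen`` file.

    Default dialect is headerless two-column (person_id, phenotype);
    ``id_style='fid_iid'`` duplicates the id into family/individual columns
    per GCTA convention.  ``header=True`` prepends column names.
    """
    if id_style not in ("single", "fid_iid"):
        raise ValueError(f"unknown id_style {id_style!r}")
    df = pheno.df
    traits = sorted(df["causal_mutation_id"].unique())
    if trait_id is None:
        if len(traits) > 1:
            raise ValueError(
                f"phenotype table holds traits {traits}; pass trait_id to select one"
            )
        trait_id = traits[0] if traits else 0
    sub = df[df["causal_mutation_id"] == trait_id]
    values = sub["phenotype"].to_numpy(dtype=float)
    if values.size and not np.isfinite(values).all():
        bad = sub["individual_id"].iloc[int(np.flatnonzero(~np.isfinite(values))[0])]
        raise ValueError(f"non-finite phenotype for individual {bad}")
    with open(path, "w") as fh:
        if header:
            if id_style == "fid_iid":
                fh.write("FID\tIID\tphenotype\n")
            else:
                fh.write("person_id\tphenotype\n")
        for pid, val in zip(sub["individual_id"], values):
            if id_style == "fid_iid":
                fh.write(f"{pid}\t{pid}\t{float(val)!r}\n")
            else:
                fh.write(f"{pid}\t{float(val)!r}\n")


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write an intermediate pipeline table as TSV with a header."""
    df.to_csv(path, sep="\t", index=False)
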