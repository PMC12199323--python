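"""Input readers and feature builders.

Expression is log-transformed TPM; mutations are binarized per driver gene
(non-synonymous variant present vs wild type); drugs are 1024-bit folded Morgan
fingerprints; cell-drug response pairs are deduplicated with a source-precedence
rule (newer screen beats older) and small cancer-type cohorts can be filtered.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "NONSYNONYMOUS_CLASSES",
    "binarize_mutations",
    "log_transform_expression",
    "smiles_to_fingerprint",
    "fingerprint_table",
    "assemble_pairs",
    "filter_small_groups",
    "read_matrix_tsv",
    "read_pairs_tsv",
    "read_variants_tsv",
    "read_drugs_tsv",
]

# MAF-style variant classes that alter the protein sequence (case-insensitive).
NONSYNONYMOUS_CLASSES: frozenset[str] = frozenset({
    "missense", "missense_mutation",
    "nonsense", "nonsense_mutation",
    "frame_shift_ins", "frame_shift_del",
    "frameshift_insertion", "frameshift_deletion", "frameshift",
    "splice_site",
    "in_frame_ins", "in_frame_del",
    "inframe_insertion", "inframe_deletion",
    "nonstop_mutation", "nonstop",
    "translation_start_site", "start_codon_snp",
})

# Classes that are known but do not qualify (no warning emitted).
_SYNONYMOUS_CLASSES: frozenset[str] = frozenset({
    "silent", "synonymous", "intron", "igr", "rna", "lincrna",
    "3'utr", "5'utr", "3'flank", "5'flank", "utr",
})


def binarize_mutations(
    variant_records: Iterable[tuple[str, str, str]],
    driver_genes: Iterable[str],
    sample_roster: Sequence[str] | None = None,
    qualifying_classes: frozenset[str] = NONSYNONYMOUS_CLASSES,
) -> pd.DataFrame:
    """Driver-gene x sample binary matrix from (gene, sample, variant_class) records.

    Entry (g, s) is 1 iff at least one record for (g, s) carries a qualifying
    (non-synonymous) class.  Genes outside ``driver_genes`` are dropped.  A
    variant class that is neither qualifying nor a known synonymous class
    triggers a warning and does not qualify.  Samples appear as columns if they
    carry any record, or if listed in ``sample_roster`` (all-zero columns).
    """
    drivers = sorted({str(g).strip() for g in driver_genes if str(g).strip()})
    if not drivers:
        raise ValueError("driver gene set is empty")
    driver_set = set(drivers)
    qualifying = {c.lower() for c in qualifying_classes}

    hits: set[tuple[str, str]] = set()
    samples_seen: set[str] = set()
    any_driver_record = False
    for gene, sample, vclass in variant_records:
        gene, sample = str(gene).strip(), str(sample).strip()
        cls = str(vclass).strip().lower()
        if gene not in driver_set:
            continue
        any_driver_record = True
        samples_seen.add(sample)
        if cls in qualifying:
            hits.add((gene, sample))
        elif cls not in _SYNONYMOUS_CLASSES:
            warnings.warn(f"unknown variant class {vclass!r}; treated as non-qualifying")
    if not any_driver_record:
        raise ValueError("no variant record involves a declared driver gene")

    if sample_roster is not None:
        samples = list(dict.fromkeys(str(s).strip() for s in sample_roster))
        samples_seen -= set(samples)
        samples += sorted(samples_seen)  # records outside roster still reported
    else:
        samples = sorted(samples_seen)

    mat = pd.DataFrame(0, index=drivers, columns=samples, dtype=np.int8)
    for gene, sample in hits:
        if sample in mat.columns:
            mat.loc[gene, sample] = 1
    return mat


def log_transform_expression(
    tpm: pd.DataFrame, base: float = 2.0, pseudocount: float = 1.0
) -> pd.DataFrame:
    """Entrywise log_base(x + pseudocount) of a non-negative abundance matrix."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    if base <= 1:
        raise ValueError("base must exceed 1")
    values = tpm.to_numpy(dtype=float)
    if np.any(values < 0):
        raise ValueError("expression abundances must be non-negative")
    out = np.log(values + pseudocount) / np.log(base)
    return pd.DataFrame(out, index=tpm.index, columns=tpm.columns)


def smiles_to_fingerprint(
    smiles: str, n_bits: int = 1024, radius: int = 2
) -> np.ndarray:
    """Folded circular (Morgan) fingerprint of a SMILES string as a 0/1 vector."""
    if n_bits < 1:
        raise ValueError("n_bits must be >= 1")
    from rdkit import Chem
    from rdkit.Chem import rdFingerprintGenerator

    mol = Chem.MolFromSmiles(smiles) if smiles else None
    if mol is None:
        raise ValueError(f"unparsable SMILES: {smiles!r}")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    return gen.GetFingerprintAsNumPy(mol).astype(np.int8)


def fingerprint_table(
    drug_smiles: Mapping[str, str], n_bits: int = 1024, radius: int = 2
) -> pd.DataFrame:
    """Bit x drug binary matrix of Morgan fingerprints."""
    cols = {
        drug: smiles_to_fingerprint(smi, n_bits, radius)
        for drug, smi in drug_smiles.items()
    }
    return pd.DataFrame(cols, index=pd.RangeIndex(n_bits, name="bit"))


def assemble_pairs(
    records: pd.DataFrame | Iterable[tuple],
    precedence: Sequence[str] = ("GDSC2", "GDSC1"),
) -> pd.DataFrame:
    """Deduplicated (cell_id, drug_id, ln_ic50, source) pair table.

    For a (cell, drug) pair observed under several sources, the record whose
    source tag comes first in ``precedence`` wins.  Unlisted sources rank after
    all listed ones, in input order.  Conflicting duplicates (different
    ln_ic50) within the same source are an error.
    """
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        df = pd.DataFrame(records, columns=["cell_id", "drug_id", "ln_ic50", "source"])
    required = ["cell_id", "drug_id", "ln_ic50", "source"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"pair records missing columns: {missing}")
    if df.empty:
        raise ValueError("no pair records supplied")
    df["ln_ic50"] = df["ln_ic50"].astype(float)
    if not np.isfinite(df["ln_ic50"]).all():
        raise ValueError("non-finite ln_ic50 values present")

    same_source = df.drop_duplicates()
    conflicts = same_source.duplicated(subset=["cell_id", "drug_id", "source"], keep=False)
    if conflicts.any():
        pairs = same_source.loc[conflicts, ["cell_id", "drug_id", "source"]]
        listing = pairs.drop_duplicates().to_records(index=False).tolist()
        raise ValueError(f"conflicting duplicate measurements within a source: {listing}")

    rank = {tag: i for i, tag in enumerate(precedence)}
    prio = same_source["source"].map(lambda s: rank.get(s, len(rank)))
    ordered = same_source.assign(_prio=prio).sort_values(
        "_prio", kind="stable"
    )
    out = ordered.drop_duplicates(subset=["cell_id", "drug_id"], keep="first")
    out = out.drop(columns="_prio")
    # restore the input's row order among the kept records
    return out.sort_index().reset_index(drop=True)


def filter_small_groups(
    sample_groups: Mapping[str, str], min_size: int = 10
) -> set[str]:
    """Samples whose group (e.g. cancer type) has at least ``min_size`` members."""
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    counts: dict[str, int] = {}
    for group in sample_groups.values():
        counts[group] = counts.get(group, 0) + 1
    return {s for s, g in sample_groups.items() if counts[g] >= min_size}


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    """Feature x sample TSV with an identifier first column and sample header."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any() or df.columns.duplicated().any():
        raise ValueError(f"duplicate row or column identifiers in {path}")
    return df


def read_pairs_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"cell_id": str, "drug_id": str, "source": str})
    required = {"cell_id", "drug_id", "ln_ic50"}
    if not required.issubset(df.columns):
        raise ValueError(f"pair table must have columns {sorted(required)}")
    if "source" not in df.columns:
        df["source"] = "unknown"
    return df


def read_variants_tsv(path: str | Path) -> list[tuple[str, str, str]]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene", "sample", "variant_classification"}
    if not required.issubset(df.columns):
        raise ValueError(f"variant table must have columns {sorted(required)}")
    return list(
        df[["gene", "sample", "variant_classification"]].itertuples(index=False, name=None)
    )


def read_drugs_tsv(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"drug_id", "smiles"}.issubset(df.columns):
        raise ValueError("drug table must have columns drug_id, smiles")
    return dict(zip(df["drug_id"], df["smiles"]))
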