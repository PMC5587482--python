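"""File formats: frequency tables (TSV), VCF import, configs, record output.

Frequency-table dialect: tab-separated, header row ``population<TAB><locus
labels...>``, one row per deme, frequencies as decimal numbers in [0, 1].
Round trips are lossless to 10 significant digits.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .scan import FrequencyTable, ScanResult
from .sim_core import SimParams

logger = logging.getLogger(__name__)

__all__ = [
    "read_frequency_table",
    "write_frequency_table",
    "read_population_map",
    "frequencies_from_vcf",
    "load_sim_config",
    "write_scan_result",
    "write_records_jsonl",
    "write_cross_infection_matrix",
]


def read_frequency_table(path: "str | Path") -> FrequencyTable:
    """Read a per-population allele-frequency TSV (dialect above).

    Malformed rows, out-of-range values and duplicate deme IDs are rejected
    with the offending deme/locus named in the error.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise ValueError(f"{path}: empty frequency-table file")
    lines = [ln for ln in text.splitlines() if ln.strip()]
    header = lines[0].split("\t")
    if len(header) < 2 or header[0] != "population":
        raise ValueError(
            f"{path}: header must be 'population<TAB>locus...', got {lines[0]!r}"
        )
    loci = header[1:]
    demes: list[str] = []
    rows: list[list[float]] = []
    for ln_no, ln in enumerate(lines[1:], start=2):
        parts = ln.split("\t")
        if len(parts) != len(header):
            raise ValueError(
                f"{path}: line {ln_no} has {len(parts)} fields, expected {len(header)}"
            )
        demes.append(parts[0])
        try:
            rows.append([float(v) for v in parts[1:]])
        except ValueError as exc:
            raise ValueError(f"{path}: line {ln_no} (deme {parts[0]!r}): {exc}") from None
    if not rows:
        raise ValueError(f"{path}: no data rows")
    # FrequencyTable validation names the deme/locus for range and duplicate errors
    return FrequencyTable(np.array(rows, dtype=float), demes, loci)


def write_frequency_table(table: FrequencyTable, path: "str | Path") -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("population\t" + "\t".join(table.loci) + "\n")
        for deme, row in zip(table.demes, table.freqs):
            fh.write(deme + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")


def read_population_map(path: "str | Path") -> dict[str, str]:
    """Two-column TSV (sample, deme) -> {sample: deme}."""
    path = Path(path)
    mapping: dict[str, str] = {}
    for ln_no, ln in enumerate(path.read_text().splitlines(), start=1):
        if not ln.strip() or ln.startswith("#"):
            continue
        parts = ln.split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}: line {ln_no}: expected 'sample<TAB>deme', got {ln!r}")
        sample, deme = parts
        if sample in mapping:
            raise ValueError(f"{path}: duplicate sample {sample!r} at line {ln_no}")
        mapping[sample] = deme
    if not mapping:
        raise ValueError(f"{path}: empty population map")
    return mapping


def frequencies_from_vcf(
    vcf_path: "str | Path", popmap_path: "str | Path"
) -> FrequencyTable:
    """Per-deme alternate-allele frequencies from a VCF of biallelic SNVs.

    Multi-allelic sites are skipped (a count is logged); missing genotypes
    are excluded from the denominator; sites with no called alleles in any
    deme are skipped. Phased and unphased genotypes are treated identically.
    Demes appear in first-seen order of the population map.
    """
    from cyvcf2 import VCF

    popmap = read_population_map(popmap_path)
    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    missing_samples = [s for s in samples if s not in popmap]
    if missing_samples:
        raise ValueError(
            f"{vcf_path}: samples absent from population map: {missing_samples}"
        )
    deme_order = list(dict.fromkeys(popmap.values()))
    deme_of_sample = np.array([deme_order.index(popmap[s]) for s in samples])
    n_demes = len(deme_order)

    loci: list[str] = []
    freq_rows: list[np.ndarray] = []
    n_multi = 0
    n_uncalled = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        # genotype array: (n_samples, ploidy+1); last column is phasing flag
        gt = np.asarray(var.genotype.array())[:, :-1]
        alt = np.zeros(n_demes)
        tot = np.zeros(n_demes)
        for allele_col in gt.T:
            called = allele_col >= 0
            np.add.at(tot, deme_of_sample[called], 1)
            np.add.at(alt, deme_of_sample[called], allele_col[called])
        if np.any(tot == 0):
            n_uncalled += 1
            continue
        label = f"{var.CHROM}:{var.POS}"
        loci.append(label)
        freq_rows.append(alt / tot)
    if n_multi:
        logger.info("skipped %d multi-allelic sites in %s", n_multi, vcf_path)
    if n_uncalled:
        logger.info(
            "skipped %d sites with a deme lacking any called genotype in %s",
            n_uncalled,
            vcf_path,
        )
    if not loci:
        raise ValueError(f"{vcf_path}: no usable biallelic sites")
    return FrequencyTable(np.stack(freq_rows, axis=1), deme_order, loci)


def load_sim_config(path: "str | Path") -> SimParams:
    """Read SimParams from a JSON or YAML file; absent fields keep defaults.

    Defaults are the midpoints of the study parameter ranges (see
    :class:`coevoscan.experiments.ParameterRanges`).
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        import yaml

        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a mapping of SimParams fields")
    valid = set(SimParams.__dataclass_fields__)
    unknown = set(data) - valid
    if unknown:
        raise ValueError(f"{path}: unknown fields {sorted(unknown)}")
    return SimParams(**data)


def write_scan_result(result: ScanResult, path: "str | Path") -> None:
    """Write the long-format per-pair scan table as TSV."""
    result.to_long_frame().to_csv(path, sep="\t", index=False)


def write_records_jsonl(records: Iterable, path: "str | Path") -> None:
    """Replicate records as JSON lines (one record per line)."""
    with Path(path).open("w") as fh:
        for rec in records:
            fh.write(json.dumps(rec.to_dict()) + "\n")


def write_cross_infection_matrix(
    P: np.ndarray, path: "str | Path", deme_labels: "list[str] | None" = None
) -> None:
    """N x N infection-rate matrix as TSV, deme labels on both axes."""
    P = np.asarray(P)
    labels = deme_labels or [f"pop{i}" for i in range(P.shape[0])]
    df = pd.DataFrame(P, index=labels, columns=labels)
    df.index.name = "parasite_origin"
    df.to_csv(path, sep="\t")
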