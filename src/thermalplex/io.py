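"""Readers and writers for the toolkit's table, sequence and image formats.

Panels travel as TSV with one row per domain (columns: name, domain,
sequence, tm_C, dH_kcal, conc_M, fluor); spectra as CSV plus a JSON
sidecar of summaries; sequences as FASTA; count matrices as CSV.  All
tables are written with fixed column order and '.' decimals so identical
inputs reproduce byte-identical files.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Dict, List, Optional, Union

import numpy as np
import pandas as pd
import tifffile
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .panel import ChannelPanel, DesignGrid
from .spectrum import (
    DEFAULT_DH_BARCODE,
    DEFAULT_DH_QUENCHER,
    ThermalProbeSet,
    ThermalSpectrum,
    thermal_spectrum,
)
from .thermo import BindingConditions, duplex_thermo_from_sequence, melting_temperature

__all__ = [
    "read_panel_table",
    "write_panel_table",
    "write_spectrum",
    "read_fasta",
    "write_fasta",
    "read_counts_csv",
    "write_counts_csv",
    "write_image",
    "read_image",
    "load_config",
    "ConfigError",
]

PANEL_COLUMNS = ["name", "domain", "sequence", "tm_C", "dH_kcal", "conc_M", "fluor"]
_DEFAULT_DH = {"barcode": DEFAULT_DH_BARCODE, "quencher": DEFAULT_DH_QUENCHER}


class ConfigError(ValueError):
    """Malformed run configuration."""


def read_panel_table(
    path: Union[str, Path],
    salt_mM: float = 195.0,
    quencher_excess_ratio: float = 1.2,
) -> List[ThermalProbeSet]:
    """Load probes from a two-rows-per-probe domain TSV.

    Each probe needs a ``barcode`` and a ``quencher`` row.  A domain with
    a sequence is parameterized by the NN model (and checked against its
    stated tm_C when both are present, warning above 2 deg C
    disagreement); otherwise tm_C plus the stated or default enthalpy is
    used.
    """
    df = pd.read_csv(path, sep="\t", dtype={"name": str, "domain": str})
    for col in ("name", "domain", "conc_M"):
        if col not in df.columns:
            raise ConfigError(f"panel table is missing required column {col!r}")
    probes = []
    for name, rows in df.groupby("name", sort=False):
        by_domain = {}
        for _, row in rows.iterrows():
            domain = row["domain"]
            if domain not in ("barcode", "quencher"):
                raise ConfigError(f"unknown domain {domain!r} for probe {name!r}")
            by_domain[domain] = row
        missing = {"barcode", "quencher"} - set(by_domain)
        if missing:
            raise ConfigError(f"probe {name!r} is missing domain(s) {sorted(missing)}")

        conc = float(by_domain["barcode"]["conc_M"])
        cond = BindingConditions(strand_conc_M=conc, salt_mM=salt_mM)
        qcond = cond.replace(strand_conc_M=conc * quencher_excess_ratio)
        fluor = str(by_domain["barcode"].get("fluor", "Alexa647"))

        thermo = {}
        for domain, dcond in (("barcode", cond), ("quencher", qcond)):
            row = by_domain[domain]
            seq = row.get("sequence")
            tm = row.get("tm_C")
            if isinstance(seq, str) and seq.strip():
                th = duplex_thermo_from_sequence(seq, salt_mM)
                if tm is not None and np.isfinite(float(tm)):
                    tm_nn = melting_temperature(th, dcond)
                    if abs(tm_nn - float(tm)) > 2.0:
                        warnings.warn(
                            f"probe {name!r} {domain}: NN Tm {tm_nn:.1f} deg C "
                            f"disagrees with stated {float(tm):.1f} deg C",
                            stacklevel=2,
                        )
            else:
                if tm is None or not np.isfinite(float(tm)):
                    raise ConfigError(
                        f"probe {name!r} {domain}: need sequence or tm_C"
                    )
                dh = row.get("dH_kcal")
                dh = (
                    float(dh)
                    if dh is not None and np.isfinite(float(dh))
                    else _DEFAULT_DH[domain]
                )
                from .thermo import thermo_from_tm

                th = thermo_from_tm(float(tm), dh, dcond)
            thermo[domain] = th

        probes.append(
            ThermalProbeSet(
                name=str(name),
                barcode=thermo["barcode"],
                quencher=thermo["quencher"],
                barcode_conditions=cond,
                quencher_conditions=qcond,
                fluor=fluor,
                quencher_excess_ratio=quencher_excess_ratio,
            )
        )
    return probes


def write_panel_table(probes: List[ThermalProbeSet], path: Union[str, Path]) -> None:
    rows = []
    for p in probes:
        for domain, th, cond in (
            ("barcode", p.barcode, p.barcode_conditions),
            ("quencher", p.quencher, p.quencher_conditions),
        ):
            rows.append(
                {
                    "name": p.name,
                    "domain": domain,
                    "sequence": "",
                    "tm_C": round(melting_temperature(th, cond), 6),
                    "dH_kcal": th.dH_kcal,
                    "conc_M": p.barcode_conditions.strand_conc_M,
                    "fluor": p.fluor,
                }
            )
    pd.DataFrame(rows, columns=PANEL_COLUMNS).to_csv(path, sep="\t", index=False)


def write_spectrum(
    spectrum: ThermalSpectrum, csv_path: Union[str, Path]
) -> None:
    """Write the curve as CSV plus a JSON sidecar of the summaries."""
    csv_path = Path(csv_path)
    pd.DataFrame(
        {"temp_C": spectrum.temps_C, "signal": spectrum.signal}
    ).to_csv(csv_path, index=False)
    sidecar = {
        "ts_C": spectrum.ts_C,
        "yield": spectrum.signal_yield,
        "width_C": spectrum.width_C,
    }
    csv_path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2) + "\n")


def read_fasta(path: Union[str, Path]) -> Dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Dict[str, str], path: Union[str, Path]) -> None:
    records = [
        SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_counts_csv(path: Union[str, Path]) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0)
    if (df.values < 0).any():
        raise ValueError("count matrix contains negative entries")
    return df


def write_counts_csv(counts: pd.DataFrame, path: Union[str, Path]) -> None:
    counts.to_csv(path)


def write_image(image: np.ndarray, path: Union[str, Path]) -> None:
    tifffile.imwrite(str(path), np.asarray(image))


def read_image(path: Union[str, Path]) -> np.ndarray:
    return tifffile.imread(str(path))


def load_config(
    path: Union[str, Path], allowed_keys: Optional[set] = None
) -> dict:
    """Load a YAML config, rejecting unknown keys when a schema is given."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ConfigError("config must be a mapping")
    if allowed_keys is not None:
        unknown = set(cfg) - allowed_keys
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
    return cfg
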