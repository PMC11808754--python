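"""Bundled compound panels.

The standard mixtures used to characterize the line-scan workflow — peptide
hormones, maltose-series carbohydrates (as sodium adducts), exogenous small
molecules, and medium-chain free fatty acids — expressed as molecular
formulas. All m/z values and envelopes are computed from the formulas at
import time, never hard-coded.
"""

from __future__ import annotations

import csv
from pathlib import Path

from .annotate import CompoundRecord

# leucine enkephalin (YGGFL) rides in the spray solvent as the lock mass
LOCKMASS_FORMULA = "C28H37N5O7"

FFA_FORMULAS = {
    "C8:0": "C8H16O2",
    "C10:0": "C10H20O2",
    "C12:0": "C12H24O2",
    "C12:1": "C12H22O2",
    "C14:0": "C14H28O2",
    "C14:1": "C14H26O2",
}

PEPTIDE_FORMULAS = {
    "VTV": "C14H27N3O5",  # Val-Thr-Val tripeptide
    "bradykinin": "C50H73N15O11",
    "angiotensin II": "C50H71N13O12",
    "substance P": "C63H98N18O13S",
    "leucine enkephalin": LOCKMASS_FORMULA,
}

# malto-oligosaccharides, (C6H10O5)n + H2O
MALTOSE_FORMULAS = {
    "M2": "C12H22O11",
    "M3": "C18H32O16",
    "M4": "C24H42O21",
    "M5": "C30H52O26",
    "M6": "C36H62O31",
}

EXOGENOUS_FORMULAS = {
    "caffeine": "C8H10N4O2",
    "sulfadimethoxine": "C12H14N4O4S",
    "sulfaguanidine": "C7H10N4O2S",
    "reserpine": "C33H40N2O9",
}


def ffa_panel() -> list[CompoundRecord]:
    """Free fatty acids, negative mode [M-H]-."""
    return [CompoundRecord(n, f, ["[M-H]-"]) for n, f in FFA_FORMULAS.items()]


def peptide_panel() -> list[CompoundRecord]:
    return [
        CompoundRecord(n, f, ["[M+H]+", "[M+2H]2+"])
        for n, f in PEPTIDE_FORMULAS.items()
    ]


def maltose_panel() -> list[CompoundRecord]:
    """Maltose series, promoted as sodium adducts."""
    return [CompoundRecord(n, f, ["[M+Na]+"]) for n, f in MALTOSE_FORMULAS.items()]


def exogenous_panel() -> list[CompoundRecord]:
    return [CompoundRecord(n, f, ["[M+H]+"]) for n, f in EXOGENOUS_FORMULAS.items()]


def standards_panel() -> list[CompoundRecord]:
    """All bundled standards (mixed polarity)."""
    return ffa_panel() + peptide_panel() + maltose_panel() + exogenous_panel()


def lockmass_record(polarity: str = "negative") -> CompoundRecord:
    adduct = "[M-H]-" if polarity == "negative" else "[M+H]+"
    return CompoundRecord("leucine enkephalin", LOCKMASS_FORMULA, [adduct])


def read_panel_csv(path: str | Path) -> list[CompoundRecord]:
    """Read a panel from CSV/TSV with columns name, formula, adducts.

    ``adducts`` is a semicolon- or pipe-separated list of adduct labels.
    """
    path = Path(path)
    delim = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    records = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter=delim):
            adducts = [
                a.strip()
                for a in row["adducts"].replace("|", ";").split(";")
                if a.strip()
            ]
            records.append(CompoundRecord(row["name"], row["formula"], adducts))
    return records


def write_panel_csv(records: list[CompoundRecord], path: str | Path) -> None:
    path = Path(path)
    delim = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delim)
        writer.writerow(["name", "formula", "adducts"])
        for rec in records:
            writer.writerow([rec.name, rec.formula, ";".join(rec.adducts)])
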