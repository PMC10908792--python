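"""Synthetic annotation reference lists and calibrant sets.

The study design consumes database export lists (formula, name, id, main
class).  Since no such export ships with the package, this module builds a
*synthetic* stand-in: a curated core of well-known breath/biofluid
metabolites plus systematically generated lipid-, carnitine- and
sugar-like compositions.  Candidate ion m/z values are kept mutually
separated so that sub-ppm annotation against the list is unambiguous —
convenient for ground-truth recovery, unlike a real database with its
isobar clashes.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .adducts import AdductRule, DEFAULT_ADDUCTS, NEGATIVE_ADDUCTS, POSITIVE_ADDUCTS, theoretical_mz
from .annotate import ReferenceRecord
from .formula import ChemicalFormula, parse_formula

AMINO = "Amino acids, peptides, and analogues"
FATTY = "Fatty acids and conjugates"
ESTERS = "Fatty acid esters"
PHOSPHO = "Glycerophospholipids"
CARBS = "Carbohydrates and carbohydrate conjugates"
ORGACID = "Organic acids and derivatives"
PURINE = "Purines and purine derivatives"
BENZENOID = "Benzene and substituted derivatives"
PRENOL = "Prenol lipids"
ORGANOOXY = "Organooxygen compounds"

#: Curated core: (formula, putative name, main class). Includes the usual
#: amino acids, TCA-cycle acids, purine bases, vitamins, carnitines and the
#: phospholipids that dominate breath-droplet metabolomes.
CURATED: List[Tuple[str, str, str]] = [
    ("C5H9NO2", "l-Proline", AMINO),
    ("C9H11NO3", "l-Tyrosine", AMINO),
    ("C5H12N2O2", "l-Ornithine", AMINO),
    ("C3H7NO3", "d-Serine", AMINO),
    ("C11H12N2O2", "l-Tryptophan", AMINO),
    ("C5H11NO2S", "l-Methionine", AMINO),
    ("C9H11NO2", "l-Phenylalanine", AMINO),
    ("C6H14N2O2", "l-Lysine", AMINO),
    ("C3H7NO2", "l-Alanine", AMINO),
    ("C2H5NO2", "Glycine", AMINO),
    ("C6H13NO2", "l-Leucine", AMINO),
    ("C5H11NO2", "l-Valine", AMINO),
    ("C5H10N2O3", "l-Glutamine", AMINO),
    ("C5H9NO4", "l-Glutamic acid", AMINO),
    ("C4H7NO4", "l-Aspartic acid", AMINO),
    ("C4H9NO3", "l-Threonine", AMINO),
    ("C6H9N3O2", "l-Histidine", AMINO),
    ("C10H17N3O6S", "Glutathione", AMINO),
    ("C14H18N2O6", "gamma-Glutamyltyrosine", AMINO),
    ("C3H7NO4S", "Cysteinesulfinic acid", AMINO),
    ("C2H7NO3S", "Taurine", AMINO),
    ("C4H7NO2", "2-Aminobut-2-enoic acid", AMINO),
    ("C9H9NO3", "Hippuric acid", BENZENOID),
    ("C9H10O4", "Homovanillic acid", BENZENOID),
    ("C11H15NO2", "N-Methylsalsolinol", BENZENOID),
    ("C8H9NO3", "Pyridoxal", ORGANOOXY),
    ("C4H6O5", "Malic acid", ORGACID),
    ("C6H8O7", "Citric acid", ORGACID),
    ("C4H6O4", "Succinic acid", ORGACID),
    ("C3H6O3", "l-Lactic acid", ORGACID),
    ("C3H4O3", "Pyruvic acid", ORGACID),
    ("C4H4O4", "Fumaric acid", ORGACID),
    ("C4H8O5", "Threonic acid", ORGACID),
    ("C7H10O6", "3-Dehydroquinic acid", ORGACID),
    ("C6H8O6", "Ascorbic acid", ORGANOOXY),
    ("C5H4N4O3", "Uric acid", PURINE),
    ("C5H4N4O", "Hypoxanthine", PURINE),
    ("C5H5N5", "Adenine", PURINE),
    ("C8H10N4O2", "Caffeine", PURINE),
    ("C4H7N3O", "Creatinine", AMINO),
    ("C6H12O6", "d-Glucose", CARBS),
    ("C6H12O5", "1,5-Anhydrosorbitol", CARBS),
    ("C12H22O11", "Sucrose", CARBS),
    ("C5H10O5", "d-Ribose", CARBS),
    ("C7H15NO3", "l-Carnitine", ESTERS),
    ("C9H17NO4", "Acetylcarnitine", ESTERS),
    ("C10H19NO4", "Propionylcarnitine", ESTERS),
    ("C16H31NO4", "Nonanoylcarnitine", ESTERS),
    ("C17H31NO4", "9-Decenoylcarnitine", ESTERS),
    ("C19H31NO4", "Dodeca-3,6,9-trienoylcarnitine", ESTERS),
    ("C14H26O2", "Myristoleic acid", FATTY),
    ("C16H32O2", "Palmitic acid", FATTY),
    ("C18H32O2", "Linoleic acid", FATTY),
    ("C18H26O3", "4-Oxo-9,11,13,15-octadecatetraenoic acid", FATTY),
    ("C16H22O3", "15-Oxo-pentadecatetraenoic acid methyl ester", FATTY),
    ("C40H80NO7P", "PC(P-18:0/14:0)", PHOSPHO),
    ("C40H80NO8P", "PC(16:0/16:0)", PHOSPHO),
    ("C28H50NO7P", "LysoPC(20:4/0:0)", PHOSPHO),
    ("C19H36O5", "DG(16:0/0:0/0:0)", PRENOL),
    ("C21H40O5", "DG(18:0/0:0/0:0)", PRENOL),
    ("C15H9FO2", "Fluoroflavone-like compound", BENZENOID),
    ("C35H66O8", "Donhexocin", PRENOL),
    ("C29H50O2", "alpha-Tocopherol", PRENOL),
]


def _generated_compositions() -> List[Tuple[str, str, str]]:
    """Deterministic lipid/carnitine/sugar-like formula families."""
    rows: List[Tuple[str, str, str]] = []
    for n in range(8, 29):  # fatty acids FA(n:d)
        for d in range(0, min(5, (n - 2) // 4) + 1):
            rows.append((f"C{n}H{2 * n - 2 * d}O2", f"FA({n}:{d})", FATTY))
    for n in range(5, 23, 2):  # hydroxy fatty acids
        for d in (0, 1, 2):
            rows.append((f"C{n}H{2 * n - 2 * d}O3", f"OH-FA({n}:{d})", FATTY))
    for n in range(4, 19, 2):  # acylcarnitines CAR(n:d)
        for d in (0, 1):
            rows.append(
                (f"C{n + 7}H{13 + 2 * n - 2 * d}NO4", f"CAR({n}:{d})", ESTERS)
            )
    for a in range(24, 39, 2):  # diacyl PCs
        for d in (0, 1, 2, 4):
            rows.append(
                (f"C{8 + a}H{16 + 2 * a - 2 * d}NO8P", f"PC({a}:{d})", PHOSPHO)
            )
    for a in range(14, 23, 2):  # lyso-PCs
        for d in (0, 1, 3):
            rows.append(
                (f"C{8 + a}H{18 + 2 * a - 2 * d}NO7P", f"LysoPC({a}:{d})", PHOSPHO)
            )
    for n in range(3, 8):  # sugar alcohols and monosaccharide-like polyols
        rows.append((f"C{n}H{2 * n + 2}O{n}", f"Polyol(C{n})", CARBS))
    for n in range(2, 13):  # N-acyl amino-acid-like compositions
        rows.append((f"C{n + 2}H{2 * n + 3}NO3", f"N-AcylGly({n})", AMINO))
    for n in range(5, 16):  # dicarboxylic acids
        rows.append((f"C{n}H{2 * n - 2}O4", f"DCA({n})", ORGACID))
    return rows


def build_reference_list(
    n_max: Optional[int] = None,
    min_separation_ppm: float = 5.0,
    adducts: Sequence[AdductRule] = tuple(DEFAULT_ADDUCTS),
) -> List[ReferenceRecord]:
    """Build the default synthetic reference list.

    Curated entries come first (they win first-listed ties downstream),
    then the generated families.  A candidate is dropped when any of its
    ion m/z values (over the default adduct set, per polarity) falls within
    ``min_separation_ppm`` of an already accepted candidate's ion, so every
    surviving record is annotatable without isobaric ambiguity.
    """
    accepted: List[ReferenceRecord] = []
    taken: Dict[str, List[float]] = {"positive": [], "negative": []}
    seen_formulas = set()
    idx = 0
    for formula_str, name, main_class in CURATED + _generated_compositions():
        if formula_str in seen_formulas:
            continue
        formula = parse_formula(formula_str)
        ion_mzs = {
            pol: [
                theoretical_mz(formula, ad)
                for ad in adducts
                if ad.polarity == pol
            ]
            for pol in ("positive", "negative")
        }
        clash = False
        for pol, mzs in ion_mzs.items():
            existing = np.asarray(taken[pol])
            for mz in mzs:
                if existing.size and np.min(
                    np.abs(existing - mz)
                ) < mz * min_separation_ppm * 1e-6:
                    clash = True
                    break
            if clash:
                break
        if clash:
            continue
        idx += 1
        accepted.append(
            ReferenceRecord(
                formula=formula,
                putative_name=name,
                db_id=f"SYN{idx:05d}",
                main_class=main_class,
            )
        )
        seen_formulas.add(formula_str)
        for pol, mzs in ion_mzs.items():
            taken[pol].extend(mzs)
        if n_max is not None and len(accepted) >= n_max:
            break
    return accepted


#: Calibrant formulas spanning the detection range; matched as [M+H]+ or
#: [M-H]- depending on acquisition polarity.
CALIBRANT_FORMULAS = [
    "C2H5NO2",   # glycine, 76 m/z region
    "C5H9NO2",   # proline
    "C6H12O6",   # glucose
    "C9H11NO2",  # phenylalanine
    "C6H8O7",    # citric acid
    "C10H17N3O6S",  # glutathione
    "C16H32O2",  # palmitic acid
    "C12H22O11",  # sucrose
    "C28H50NO7P",  # lyso-PC
    "C40H80NO8P",  # DPPC
]


def default_calibrants() -> List[Tuple[ChemicalFormula, AdductRule]]:
    """Calibrant (formula, adduct) pairs for both polarities."""
    out: List[Tuple[ChemicalFormula, AdductRule]] = []
    for fs in CALIBRANT_FORMULAS:
        f = parse_formula(fs)
        out.append((f, POSITIVE_ADDUCTS[0]))
        out.append((f, NEGATIVE_ADDUCTS[0]))
    return out
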