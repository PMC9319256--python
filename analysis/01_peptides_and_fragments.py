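"""Peptide bookkeeping for the two candidate NLS regions of PADI4.

Computes average masses (free and synthesis-capped), theoretical
random-coil hydrodynamic radii, and the sliding-window fragment tables
used for piecewise docking.  Findings: the 27-mer NLS1 peptide weighs
2819.2 Da (14.3 Å random-coil radius) and tiles into 11 seven-residue
fragments; the extended NLS2 region (residues 490-526) tiles into 16.
"""

import json
from pathlib import Path

import pandas as pd

from bindlab import peptides as pep

RESULTS = Path(__file__).resolve().parents[1] / "results"
RESULTS.mkdir(exist_ok=True)


def fragment_table(parent: pep.PeptideSequence) -> pd.DataFrame:
    frags = pep.make_fragments(parent, window=7, step=2)
    return pd.DataFrame(
        [
            {
                "fragment_id": i,
                "start_number": f.start_number,
                "end_number": f.end_number,
                "sequence": f.residues,
                "nterm_cap": f.n_term_cap,
                "cterm_cap": f.c_term_cap,
            }
            for i, f in enumerate(frags)
        ]
    )


def main() -> None:
    nls1_free = pep.PeptideSequence("AKKKSTGSSTWPLDPGVEVTLTMKVAS", start_number=58)
    nls1_capped = pep.PeptideSequence(nls1_free.residues, start_number=58,
                                      n_term_cap="acetyl", c_term_cap="amide")
    nls2_free = pep.PeptideSequence("YKLFQEQQNEGHGEALLFEGIKKKKQQKI", start_number=498)
    nls2_capped = pep.PeptideSequence(nls2_free.residues, start_number=498,
                                      n_term_cap="acetyl", c_term_cap="amide")

    summary = {}
    for name, seq in (
        ("nls1_free", nls1_free),
        ("nls1_acetyl_amide", nls1_capped),
        ("nls2_free", nls2_free),
        ("nls2_acetyl_amide", nls2_capped),
    ):
        mass = pep.average_mass(seq)
        summary[name] = {
            "length": len(seq),
            "mass_Da": round(mass, 2),
            "random_coil_rh_A": round(pep.random_coil_rh(mass), 1),
        }

    t1 = fragment_table(pep.PeptideSequence(nls1_free.residues, start_number=58,
                                            c_term_cap="amide"))
    t2 = fragment_table(pep.NLS2_REGION_PADI4)
    t1.to_csv(RESULTS / "fragments_nls1.csv", index=False)
    t2.to_csv(RESULTS / "fragments_nls2_region.csv", index=False)
    summary["n_fragments_nls1"] = len(t1)
    summary["n_fragments_nls2_region"] = len(t2)

    (RESULTS / "peptides_summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    print(json.dumps(summary, indent=2))
    print(f"fragment tables -> {RESULTS}/fragments_nls1.csv, fragments_nls2_region.csv")


if __name__ == "__main__":
    main()
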