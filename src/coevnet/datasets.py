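"""Published reference data for the phosphomannomutase/phosphoglucomutase study.

Two small tables transcribed from the experimental characterization of the
Pseudomonas aeruginosa enzyme:

* steady-state kinetic parameters for wild type, five single alanine mutants
  and three double mutants (kcat in s⁻¹, Km in µM, kcat/Km in µM⁻¹ s⁻¹; the
  published kcat/Km values are carried explicitly because they were rounded
  independently of kcat and Km);
* the five largest cliques (A–E) of the coevolving-residue network, as
  residue numbers of the 463-residue reference enzyme, plus the residue
  types observed at each position.
"""

from __future__ import annotations

from .kinetics import KineticParams


def pmm_pgm_kinetics() -> dict[str, KineticParams]:
    """Steady-state kinetics of the characterized enzyme variants."""
    rows = [
        # name, kcat, kcat_se, Km, Km_se, spec (published), spec_se
        ("WT",          6.96,  0.19, 28.0,  3.0, 0.25,     0.03),
        ("D261A",       0.43,  0.02, 54.0,  7.0, 0.008,    0.001),
        ("K285A",       1.682, 0.009, 66.7, 1.1, 0.0252,   0.0004),
        ("E375A",       3.02,  0.09, 11.5,  1.5, 0.26,     0.03),
        ("R410A",       2.07,  0.03, 18.5,  1.3, 0.112,    0.008),
        ("R432A",       0.96,  0.02, 40.0,  3.0, 0.024,    0.002),
        ("K285A/R410A", 0.89,  0.02, 56.0,  4.0, 0.016,    0.001),
        ("K285A/R432A", 0.047, 0.002, 190.0, 20.0, 0.000247, 0.000003),
        ("R410A/R432A", 0.122, 0.009, 28.0, 11.0, 0.004,   0.002),
    ]
    return {
        name: KineticParams(name=name, kcat=kcat, km=km, spec=spec,
                            kcat_se=kcat_se, km_se=km_se, spec_se=spec_se)
        for name, kcat, kcat_se, km, km_se, spec, spec_se in rows
    }


def top_clique_table() -> dict[str, frozenset[int]]:
    """The five largest coevolving-residue cliques (A–E), by residue number."""
    return {
        "A": frozenset({88, 261, 284, 285, 410}),
        "B": frozenset({249, 331, 374, 419, 430}),
        "C": frozenset({285, 331, 341, 410, 419, 430}),
        "D": frozenset({285, 331, 341, 419, 430, 432}),
        "E": frozenset({331, 341, 374, 419, 430, 432}),
    }


#: Residue types observed at each top-clique position in the family alignment.
TOP_CLIQUE_RESIDUE_TYPES: dict[int, str] = {
    88: "DEP", 249: "AFG", 261: "DSY", 284: "LPV", 285: "IKR", 331: "FY",
    341: "DST", 374: "GP", 410: "RST", 419: "LN", 430: "RV", 432: "NRV",
}
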