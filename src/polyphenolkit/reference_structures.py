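"""Reference structures used in worked examples and verification checks.

``CANONICAL`` holds literature structures of well-characterized dietary
flavonoids (SMILES written from their systematic names).

``SYNTHETIC_ISOMERS`` holds *synthetic* stand-in structures for two large
ellagitannins: hand-built inositol polygalloate isomers constructed to have
exactly the authentic molecular formulas (C48H28O30 for the punicalagin
stand-in, C82H54O52 for the Sanguiin H-6 stand-in). They are not the true
connectivities — average molecular weight depends only on the molecular
formula, which is what the mass checks exercise.
"""

CANONICAL: dict[str, str] = {
    # (3R)-7-hydroxy-2',4'-dimethoxyisoflavanone
    "sativanone": "COc1ccc(C2COc3cc(O)ccc3C2=O)c(OC)c1",
    # 7-hydroxy-4'-methoxyisoflavanone
    "dihydroformononetin": "COc1ccc(C2COc3cc(O)ccc3C2=O)cc1",
    # 7,4'-dihydroxyflavanone
    "liquiritigenin": "O=C1CC(c2ccc(O)cc2)Oc2cc(O)ccc21",
    # 5,7,4'-trihydroxyflavanone
    "naringenin": "O=C1CC(c2ccc(O)cc2)Oc2cc(O)cc(O)c21",
    # 3,5,7,3',4'-pentahydroxyflavone
    "quercetin": "O=c1c(O)c(-c2ccc(O)c(O)c2)oc2cc(O)cc(O)c12",
}

SYNTHETIC_ISOMERS: dict[str, tuple[str, str]] = {
    # name -> (molecular formula, synthetic isomer SMILES)
    "punicalagin": (
        "C48H28O30",
        "C1(OC(=O)c2cc(O)c(O)c(O)c2%11)C(OC(=O)c2c%11c(O)c(O)c(O)c2%12)"
        "C(OC(=O)c2c%12c(O)c(O)c(O)c2%13)C(OC(=O)c2cc(O)c(O)c(O)c2%13)"
        "C(OC(=O)c2cc(O)c(O)c(O)c2%14)C1OC(=O)c2cc(O)c(O)c(O)c2%14",
    ),
    "sanguiin H-6": (
        "C82H54O52",
        "C1(O)C(OC(=O)c2cc(O)c(O)c(O)c2%11)C(OC(=O)c2c%11c(O)c(O)c(O)c2)"
        "C(OC(=O)c2cc(O)c(O)c(O)c2%12)C(OC(=O)c2c%12c(O)c(O)c(O)c2)"
        "C1OC(=O)c2cc(O)c(O)c(O)c2%21."
        "C3(O)C(OC(=O)c2cc(O)c(O)c(O)c2%13)C(OC(=O)c2c%13c(O)c(O)c(O)c2)"
        "C(OC(=O)c2cc(O)c(O)c(O)c2%14)C(OC(=O)c2c%14c(O)c(O)c(O)c2)"
        "C3OC(=O)c2c%21cc(O)c(O)c2O",
    ),
}

#: published molecular weights (g/mol) for the three misfiled ellagitannins
ELLAGITANNIN_MASSES: dict[str, float] = {
    "Lambertianin C": 2805.91,
    "Sanguiin H-6": 1871.28,
    "Punicalagin": 1084.72,
}

__all__ = ["CANONICAL", "SYNTHETIC_ISOMERS", "ELLAGITANNIN_MASSES"]
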