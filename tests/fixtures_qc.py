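"""Hand-built aligned-matrix fixture with planted QC violations.

Six study spectra (two conditions x three replicates) and ten blanks.
Every feature is constructed to pass or fail exactly one QC rule:

* ``floor``   per-spectrum minimum-intensity peaks (fail the raised limit)
* ``C_lim``   intensity 104 with spectrum minimum 100 (fails 1.05 x 100)
* ``E_ok``    intensity 106 (just above the raised limit; compliant)
* ``B_occ``   detected in only two study spectra (fails >= 3 occurrence)
* ``G_snr``   sample S/N 4, one blank at S/N 100 (fails the 20x blank rule)
* ``H_maj``   strong in samples but present in 7 of 10 blanks (fails 7-of-10)
* ``I_ok``    strong in samples, present in only 6 blanks at low S/N (compliant)
* ``A_ok``    strong everywhere in samples, absent from blanks (compliant)
"""

from vdomics.assignment import Assignment
from vdomics.datamodel import Peak, SampleMeta, parse_formula

FORMULAS = {
    "A_ok": "C10H20O5",
    "B_occ": "C11H22O5",
    "C_lim": "C12H24O5",
    "E_ok": "C13H26O5",
    "G_snr": "C14H28O5",
    "H_maj": "C15H30O5",
    "I_ok": "C16H32O5",
}

COMPLIANT = {"A_ok", "E_ok", "I_ok"}
VIOLATING = {"B_occ", "C_lim", "G_snr", "H_maj"}


def build_fixture():
    study = [f"s{i}" for i in range(1, 7)]
    blanks = [f"b{i}" for i in range(1, 11)]
    metas = [
        SampleMeta(s, "surface", "treatment" if i < 3 else "control", 0, i % 3 + 1)
        for i, s in enumerate(study)
    ]
    metas += [SampleMeta(b, "surface", "blank", 0, i + 1) for i, b in enumerate(blanks)]

    mz = {name: 200.0 + 10 * i for i, name in enumerate(FORMULAS)}
    assignments = {}
    for j, s in enumerate(study):
        asgs = []

        def add(name, intensity, snr):
            asgs.append(
                Assignment(
                    peak=Peak(mz[name], intensity, snr),
                    formula=parse_formula(FORMULAS[name]),
                    error_ppm=0.0,
                    status="assigned",
                )
            )

        add("A_ok", 1000.0, 50.0)
        if j < 2:
            add("B_occ", 1000.0, 50.0)
        add("C_lim", 104.0, 5.2)
        add("E_ok", 106.0, 5.3)
        add("G_snr", 400.0, 4.0)
        add("H_maj", 1000.0, 50.0)
        add("I_ok", 1000.0, 50.0)
        # per-spectrum minimum: an unassigned noise peak at intensity 100
        asgs.append(
            Assignment(peak=Peak(300.0 + j * 5.0, 100.0, 5.0), formula=None,
                       error_ppm=None, status="no_candidate")
        )
        assignments[s] = asgs

    for i, b in enumerate(blanks):
        asgs = [
            # blank floor so the raised limit does not empty the blank
            Assignment(peak=Peak(400.0 + i * 5.0, 100.0, 5.0), formula=None,
                       error_ppm=None, status="no_candidate")
        ]
        if i == 0:
            asgs.append(Assignment(peak=Peak(mz["G_snr"], 2000.0, 100.0),
                                   formula=parse_formula(FORMULAS["G_snr"]),
                                   error_ppm=0.0, status="assigned"))
        if i < 7:
            asgs.append(Assignment(peak=Peak(mz["H_maj"], 300.0, 5.0),
                                   formula=parse_formula(FORMULAS["H_maj"]),
                                   error_ppm=0.0, status="assigned"))
        if i < 6:
            asgs.append(Assignment(peak=Peak(mz["I_ok"], 300.0, 5.0),
                                   formula=parse_formula(FORMULAS["I_ok"]),
                                   error_ppm=0.0, status="assigned"))
        assignments[b] = asgs

    return assignments, metas
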