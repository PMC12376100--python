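"""Unit conversion constants (CODATA 2018).

Internal conventions across the package:

* geometry in angstrom at the API boundary, bohr inside field/DVR kernels;
* energies in hartree (E_h) inside the solvers, cm^-1 at the API boundary;
* masses in amu at the API boundary, electron masses internally;
* partial charges in elementary charges e;
* Lennard-Jones epsilon in kJ/mol (force-field convention), sigma in angstrom;
* time in ps, frequencies in cm^-1 (spectra) or rad/ps (phase integrals).

Every conversion lives here so that a unit bug has exactly one place to hide.
"""

import math

#: hartree -> cm^-1
HARTREE_TO_INVCM = 219474.6313632

#: hartree -> kJ/mol
HARTREE_TO_KJMOL = 2625.4996394799

#: kJ/mol -> hartree
KJMOL_TO_HARTREE = 1.0 / HARTREE_TO_KJMOL

#: bohr -> angstrom
BOHR_TO_ANGSTROM = 0.529177210903

#: angstrom -> bohr
ANGSTROM_TO_BOHR = 1.0 / BOHR_TO_ANGSTROM

#: unified atomic mass unit -> electron mass
AMU_TO_ME = 1822.888486209

#: speed of light in cm/ps (used to convert cm^-1 <-> rad/ps)
C_CM_PER_PS = 0.0299792458

#: cm^-1 -> angular frequency in rad/ps
INVCM_TO_RAD_PER_PS = 2.0 * math.pi * C_CM_PER_PS

#: rad/ps -> cm^-1
RAD_PER_PS_TO_INVCM = 1.0 / INVCM_TO_RAD_PER_PS
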