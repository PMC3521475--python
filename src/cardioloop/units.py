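"""Unit conventions used throughout the package.

Everything public is expressed in conventional hemodynamic units:

========================  =============================================
quantity                  unit
========================  =============================================
pressure                  mmHg
volume                    mL
flow                      mL/s (cardiac output is reported in mL/min)
resistance                U, where 1 U = 1 mmHg per mL/s (= 1 mmHg*s/mL)
compliance                mL/mmHg
time                      s
sympathetic drive (Sy)    FGU (factor-of-gain units, dimensionless)
========================  =============================================

The resistance unit U comes from the electrical-analog tradition of
lumped-parameter circulation models (voltage <-> pressure, current <->
flow, charge <-> volume, 1 megaohm <-> 1 U).  The inotropic drive Sy is
dimensionless; the ventricular contractility effector saturates at
``FGU_LIMIT`` FGU regardless of how large the drive signal becomes.
"""

#: 1 U expressed in mmHg*s/mL.
U_IN_MMHG_S_PER_ML: float = 1.0

#: Saturation ceiling of the inotropic (contractility) effector, in FGU.
FGU_LIMIT: float = 8.0

#: Conversion factor: flow in mL/s times this is cardiac output in mL/min.
MLS_TO_MLMIN: float = 60.0
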