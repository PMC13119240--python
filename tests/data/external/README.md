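# External crystal structures (optional)

Comparator tests and `analysis/05_crystal_comparators.py` use real crystal
structures when CIF files are placed here. They are not redistributed with
the package; export them from the Cambridge Structural Database under your
own license:

- `BICCIZ07.cif` — nifedipine, alpha polymorph
- `BICCIZ03.cif` — nifedipine, beta polymorph
- `DONTIJ.cif`   — felodipine, form I
- `DONTIJ01.cif` — felodipine, form II

Without these files the corresponding tests are skipped and the analysis
script reports which comparators were unavailable.
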