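units: mm
source_offsets:
- - 10.0
  - 0.0
- - -4.999999999999998
  - 8.660254037844387
- - -5.000000000000004
  - -8.660254037844384
detector_offsets:
- - 0.0
  - 0.0
- - 5.000000000000001
  - 8.660254037844386
- - -10.0
  - 1.2246467991473533e-15
- - 5.000000000000001
  - -8.660254037844386
wavelengths_nm:
- 735.0
- 850.0
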