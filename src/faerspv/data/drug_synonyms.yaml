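# Minimal trade-name / code-name synonym sets for the three target
# PD-1/PD-L1 inhibitors.  Editable; full RxNorm mapping is out of scope.
NIVOLUMAB:
  - OPDIVO
PEMBROLIZUMAB:
  - KEYTRUDA
  - LAMBROLIZUMAB
  - MK-3475
ATEZOLIZUMAB:
  - TECENTRIQ
  - MPDL3280A
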