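code,preferred_term
10021036,Hyponatremia
10005802,Blood sodium decreased
10053198,Inappropriate antidiuretic hormone secretion
10005800,Blood sodium abnormal
10069350,Osmotic demyelination syndrome
10021037,Hyponatremic syndrome
10070604,Rapid correction of hyponatremia
10066151,Hyponatremic encephalopathy
10074867,Hypoosmolar state
10049222,Neonatal hyponatremia
10005335,Blood antidiuretic hormone increased
10002776,Antidiuretic hormone abnormality
10075865,Hyponatremic coma
10005332,Blood antidiuretic hormone abnormal
10014149,Ectopic antidiuretic hormone secretion
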