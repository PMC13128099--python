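source_code,target
331.83,292.2
294.9,292.2
G31.84,292.2
F06.7,292.2
F09,292.2
R41.840,292.2
R41.841,292.2
R41.89,292.2
R41.9,292.2
331.0,290.11
G30,290.11
G30.0,290.11
G30.1,290.11
G30.8,290.11
G30.9,290.11
I10,401.1
401.1,401.1
E11.9,250.2
250.00,250.2
E78.5,272.1
272.4,272.1
I48.91,427.2
427.31,427.2
N39.0,591
599.0,591
F32.9,296.2
311,296.2
R53.83,798
780.79,798
M54.5,760
724.2,760
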