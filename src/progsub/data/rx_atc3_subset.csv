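source_code,target
997224,N06D
310436,N06D
704,N06D
29046,C09A
18867,C07A
35296,C09A
83367,C10A
36567,C10A
6809,A10B
4821,A10B
321988,N06A
36437,N06A
1191,N02B
161,N02B
11289,B01A
32968,B01A
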