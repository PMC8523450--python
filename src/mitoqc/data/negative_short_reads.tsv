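sample	total_mapped	reads_below_80bp
Ctrl-1.1	2972	1762
Ctrl-2.1	7244	3958
Ctrl-3.1	3049	2094
Ctrl-4.1	2829	1807
Ctrl-4.2	6301	5494
Ctrl-4.3	2963	1852
Ctrl-4.4	6386	4982
Ctrl-5.1	8764	6334
Ctrl-5.2	6949	5247
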