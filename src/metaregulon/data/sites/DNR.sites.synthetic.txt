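# synthetic aligned binding sites for the DNR PWM (one per line)
GGCGGCGGGCGGGGG
CGCGGCCGCCGCCCC
GGCGGCGGGCGGGGG
CGCGGCCGCCGCCCC
GGCGGCGGGCGGGGG
CGCGGCCGCCGCCCC
GGCGGCGGGCGGGGG
CGCGGCCGCCGCCCC
GGCGGCGGGCGGGGG
CGCGGCCGCCGCCCC
GGCGGCGGGCGGGGG
CGCGGCCGCCGCCCC
GGCGGCGGGCGGGGG
CGCGGCCGCCGCCCC
GGCGGCGGGCGGGGG
CGCGGCCGCCGCCCC
GGCGGCGGGCGGGGG
CGCGGCCGCCGCCCC
GGCGGCGGGCGGGGG
CGCGGCCGCCGCCCC
GGCGGCGGGCGGGGG
CGCGGCCGCCGCCCC
GGCGGCGGGCGGGGG
CGCGGCCGCCGCCCC
GGCGGCGGGCGGGGG
CGCGGCCGCCGCCCC
GGCGGCGGGCGGGGG
CGCGGCCGCCGCCCC
GGCGGCGGGCGGGGG
CGCGGCCGCCGCCCC
GGCGGCGGGCGGGGG
CGCGGCCGCCGCCCC
GGCGGCGGGCGGGGG
CGCGGCCGCCGCCCC
GGCGGCGGGCGGGGG
CGCGGCCGCCGCCCC
GGCGGCGGGCGGGGG
CGCGGCCGCCGCCCC
GGCGGCGGGCGGGGG
CGCGGCCGCCGCCCC
GGCGGCGGGCGGGGG
CGCGGCCGCCGCCCC
GGCGGCGGGCGGGGG
CGCGGCCGCCGCCCC
GGCGGCGGGCGGGGG
CGCGGCCGCCGCCCC
GGCGGCGGGCGGGGG
CGCGGCCGCCGCCCC
GGCGGCGGGCGGGGG
CGCGGCCGCCGCCCC
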