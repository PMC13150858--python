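Name: Akesuxiaozao; fingerprint code: C/T G/A T/A T/T G/A A/A T/T A/A T/T G/G C/C G/G A/A C/C A/G A/A A/A C/C A/A A/A G/T A/A T/C C/T T/C T/T C/T A/G C/C G/T G/G G/A A/G G/A C/T C/A C/T A/G T/C G/G C/C G/G C/C A/G A/A T/T C/T C/C T/T C/G T/G G/A T/C C/C G/G C/T A/A A/A A/A T/A C/A G/A G/G T/C A/G G/G C/C C/C T/T A/A A/G C/C C/C A/A T/C C/A C/C G/G C/C T/T T/T G/G G/A A/A C/T A/C A/A A/G G/T G/A T/G A/G C/C G/G C/C G/T T/C A/G T/C T/A
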