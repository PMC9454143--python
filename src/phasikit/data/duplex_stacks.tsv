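# Nearest-neighbor stack free energies (kcal/mol) for RNA duplexes.
# pair columns give (5' strand base, 3' strand base); stack is pair1 over pair2
# reading 5'->3' on the first strand. Watson-Crick stacks use the standard
# nearest-neighbor values; stacks containing G:U wobble pairs use class
# averages (-1.3 one wobble, -0.5 two wobbles). Version 1.
pair1	pair2	dG
AU	AU	-0.93
AU	UA	-1.1
AU	CG	-2.24
AU	GC	-2.08
AU	GU	-1.3
AU	UG	-1.3
UA	AU	-1.33
UA	UA	-0.93
UA	CG	-2.35
UA	GC	-2.11
UA	GU	-1.3
UA	UG	-1.3
CG	AU	-2.11
CG	UA	-2.08
CG	CG	-3.26
CG	GC	-2.36
CG	GU	-1.3
CG	UG	-1.3
GC	AU	-2.35
GC	UA	-2.24
GC	CG	-3.42
GC	GC	-3.26
GC	GU	-1.3
GC	UG	-1.3
GU	AU	-1.3
GU	UA	-1.3
GU	CG	-1.3
GU	GC	-1.3
GU	GU	-0.5
GU	UG	-0.5
UG	AU	-1.3
UG	UA	-1.3
UG	CG	-1.3
UG	GC	-1.3
UG	GU	-0.5
UG	UG	-0.5
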