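# Default duplex energy parameters (kcal/mol, 37 C).
# Stack rows: stack<TAB>P1<TAB>P2<TAB>dG where P1=(query base, target base) of the
# 5'-side pair along the query and P2 the next pair; the physical step is
# 5'-q1 q2-3' / 3'-t1 t2-5'.  Watson-Crick steps carry the standard Turner
# nearest-neighbour free energies; wobble-containing steps carry Turner-style
# values in the published range.  Reversal symmetry dG(P1,P2)=dG(flip(P2),flip(P1))
# is satisfied throughout.
param	loop_open	4.0
param	loop_extend	0.3
param	init_penalty	0.0
stack	AU	AU	-0.93
stack	AU	UA	-1.10
stack	UA	AU	-1.33
stack	CG	UA	-2.08
stack	CG	AU	-2.11
stack	GC	UA	-2.24
stack	GC	AU	-2.35
stack	CG	GC	-2.36
stack	GC	GC	-3.26
stack	CG	CG	-3.26
stack	GC	CG	-3.42
stack	UA	UA	-0.93
stack	UA	CG	-2.35
stack	UA	GC	-2.11
stack	AU	CG	-2.24
stack	AU	GC	-2.08
stack	GU	UA	-1.36
stack	AU	UG	-1.36
stack	UG	UA	-0.55
stack	AU	GU	-0.55
stack	UG	AU	-1.00
stack	UA	GU	-1.00
stack	GU	AU	-1.27
stack	UA	UG	-1.27
stack	UG	CG	-1.53
stack	GC	GU	-1.53
stack	GU	CG	-2.51
stack	GC	UG	-2.51
stack	UG	GC	-1.41
stack	CG	GU	-1.41
stack	GU	GC	-2.11
stack	CG	UG	-2.11
stack	GU	GU	-0.50
stack	UG	UG	-0.50
stack	GU	UG	1.29
stack	UG	GU	0.30
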