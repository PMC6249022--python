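signature	channel	probability
Signature 1	A[C>T]G	0.1716
Signature 2	T[C>T]A	0.4199
Signature 2	T[C>T]C	0.0820
Signature 6	A[T>C]G	0.0217
Signature 6	G[C>T]C	0.0773
Signature 6	A[C>T]C	0.0163
Signature 6	G[T>A]G	0.0006
Signature 6	A[C>T]G	0.0908
Signature 7	A[C>T]T	0.0043
Signature 10	C[C>G]T	0.0000
Signature 10	T[C>T]G	0.2141
Signature 13	C[C>G]C	0.0009
Signature 13	T[C>T]A	0.1138
Signature 13	T[C>T]C	0.0150
Signature 14	T[C>T]G	0.0094
Signature 20	A[C>T]C	0.0222
Signature 20	A[T>C]T	0.0073
Signature 26	A[T>C]G	0.0518
Signature 26	G[T>A]G	0.0014
Signature 26	G[C>T]G	0.0225
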