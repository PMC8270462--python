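category	probability
A[C>A]A	0.00727105
A[C>A]C	0.00450294
A[C>A]G	0.00405470
A[C>A]T	0.00474098
C[C>A]A	0.00414324
C[C>A]C	0.00406695
C[C>A]G	0.00743783
C[C>A]T	0.00524464
G[C>A]A	0.00496904
G[C>A]C	0.00664484
G[C>A]G	0.00552330
G[C>A]T	0.00319508
T[C>A]A	0.00595982
T[C>A]C	0.00462127
T[C>A]G	0.00656958
T[C>A]T	0.00405428
A[C>G]A	0.00307640
A[C>G]C	0.00424727
A[C>G]G	0.00253507
A[C>G]T	0.00354328
C[C>G]A	0.00235711
C[C>G]C	0.00268641
C[C>G]G	0.00270356
C[C>G]T	0.00315711
G[C>G]A	0.00408771
G[C>G]C	0.00474978
G[C>G]G	0.00322453
G[C>G]T	0.00475460
T[C>G]A	0.00767300
T[C>G]C	0.00327809
T[C>G]G	0.00471716
T[C>G]T	0.00344982
A[C>T]A	0.01359762
A[C>T]C	0.00809136
A[C>T]G	0.01359762
A[C>T]T	0.02229350
C[C>T]A	0.01092388
C[C>T]C	0.01735509
C[C>T]G	0.01092388
C[C>T]T	0.01233688
G[C>T]A	0.01633167
G[C>T]C	0.01638273
G[C>T]G	0.01633167
G[C>T]T	0.01269045
T[C>T]A	0.00968898
T[C>T]C	0.01589661
T[C>T]G	0.00968898
T[C>T]T	0.01503308
A[T>A]A	0.00558334
A[T>A]C	0.00443305
A[T>A]G	0.00436161
A[T>A]T	0.00553867
C[T>A]A	0.01459563
C[T>A]C	0.00285341
C[T>A]G	0.00529682
C[T>A]T	0.00798092
G[T>A]A	0.00884687
G[T>A]C	0.00585613
G[T>A]G	0.00353381
G[T>A]T	0.00660601
T[T>A]A	0.00728965
T[T>A]C	0.00959793
T[T>A]G	0.00536413
T[T>A]T	0.00324243
A[T>C]A	0.02694578
A[T>C]C	0.02893471
A[T>C]G	0.02416215
A[T>C]T	0.03162609
C[T>C]A	0.01817876
C[T>C]C	0.03462052
C[T>C]G	0.02707004
C[T>C]T	0.01781827
G[T>C]A	0.03213394
G[T>C]C	0.02385501
G[T>C]G	0.01879755
G[T>C]T	0.01031948
T[T>C]A	0.03040662
T[T>C]C	0.01793990
T[T>C]G	0.02126372
T[T>C]T	0.02329615
A[T>G]A	0.01366335
A[T>G]C	0.00959487
A[T>G]G	0.00667415
A[T>G]T	0.00583940
C[T>G]A	0.01879548
C[T>G]C	0.01406769
C[T>G]G	0.00589206
C[T>G]T	0.00511409
G[T>G]A	0.00857210
G[T>G]C	0.00924449
G[T>G]G	0.00893743
G[T>G]T	0.01405254
T[T>G]A	0.00768763
T[T>G]C	0.00802029
T[T>G]G	0.00593045
T[T>G]T	0.00516041
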