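category	probability
A[C>A]A	0.00707664
A[C>A]C	0.00486606
A[C>A]G	0.00446272
A[C>A]T	0.00471002
C[C>A]A	0.00434882
C[C>A]C	0.00428170
C[C>A]G	0.00739272
C[C>A]T	0.00565222
G[C>A]A	0.00531453
G[C>A]C	0.00586837
G[C>A]G	0.00574903
G[C>A]T	0.00342491
T[C>A]A	0.00534323
T[C>A]C	0.00415499
T[C>A]G	0.00594958
T[C>A]T	0.00413251
A[C>G]A	0.00301278
A[C>G]C	0.00462923
A[C>G]G	0.00268312
A[C>G]T	0.00370415
C[C>G]A	0.00250146
C[C>G]C	0.00254251
C[C>G]G	0.00220189
C[C>G]T	0.00339811
G[C>G]A	0.00412659
G[C>G]C	0.00480772
G[C>G]G	0.00352852
G[C>G]T	0.00458786
T[C>G]A	0.00711385
T[C>G]C	0.00311391
T[C>G]G	0.00463170
T[C>G]T	0.00334759
A[C>T]A	0.01411901
A[C>T]C	0.00844185
A[C>T]G	0.01411901
A[C>T]T	0.02144103
C[C>T]A	0.01061764
C[C>T]C	0.01561044
C[C>T]G	0.01061764
C[C>T]T	0.01159064
G[C>T]A	0.01525636
G[C>T]C	0.01660249
G[C>T]G	0.01525636
G[C>T]T	0.01110663
T[C>T]A	0.01080737
T[C>T]C	0.01512319
T[C>T]G	0.01080737
T[C>T]T	0.01354396
A[T>A]A	0.00517196
A[T>A]C	0.00453904
A[T>A]G	0.00514012
A[T>A]T	0.00485809
C[T>A]A	0.01424154
C[T>A]C	0.00264187
C[T>A]G	0.00540490
C[T>A]T	0.00749063
G[T>A]A	0.00804763
G[T>A]C	0.00595827
G[T>A]G	0.00355877
G[T>A]T	0.00699335
T[T>A]A	0.00724685
T[T>A]C	0.00995170
T[T>A]G	0.00504548
T[T>A]T	0.00326251
A[T>C]A	0.02670629
A[T>C]C	0.03218596
A[T>C]G	0.02341386
A[T>C]T	0.03270334
C[T>C]A	0.02074911
C[T>C]C	0.03238649
C[T>C]G	0.02567344
C[T>C]T	0.01990240
G[T>C]A	0.03361850
G[T>C]C	0.02521625
G[T>C]G	0.01951476
G[T>C]T	0.00994884
T[T>C]A	0.03069230
T[T>C]C	0.01645658
T[T>C]G	0.02029739
T[T>C]T	0.02311719
A[T>G]A	0.01263851
A[T>G]C	0.01006734
A[T>G]G	0.00674410
A[T>G]T	0.00615382
C[T>G]A	0.01805584
C[T>G]C	0.01469083
C[T>G]G	0.00597747
C[T>G]T	0.00517512
G[T>G]A	0.00865392
G[T>G]C	0.00889738
G[T>G]G	0.00897163
G[T>G]T	0.01539859
T[T>G]A	0.00835915
T[T>G]C	0.00777674
T[T>G]G	0.00669403
T[T>G]T	0.00589009
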