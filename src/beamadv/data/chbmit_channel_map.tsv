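# Mapping from CHB-MIT channel names to 10-20 electrode labels.
# CHB-MIT records a longitudinal bipolar montage; its 22 distinct channels are
# assigned one 10-20/10-10 scalp position each (by convention, a position near
# the channel's derivation; the two leftover channels take the two leftover
# positions) so that topographic maps can be built.  This file is a
# convention, not a ground truth: edit it to change which 22 positions are
# used.  Columns: dataset channel name <TAB> 10-20 label.
FP1-F7	Fp1
F7-T7	F7
T7-P7	T7
P7-O1	P7
FP1-F3	F3
F3-C3	C3
C3-P3	P3
P3-O1	O1
FP2-F4	F4
F4-C4	C4
C4-P4	P4
P4-O2	O2
FP2-F8	Fp2
F8-T8	F8
T8-P8	T8
P8-O2	P8
FZ-CZ	Fz
CZ-PZ	Pz
T7-FT9	FT9
FT10-T8	FT10
FT9-FT10	Oz
P7-T7	Cz
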