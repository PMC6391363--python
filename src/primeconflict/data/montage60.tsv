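label	azimuth_deg	elevation_deg	role
Fp1	95.733607	17.091146	eeg
Fp2	84.266393	17.091146	eeg
AF4	66.875047	28.393750	eeg
F7	142.622632	14.477512	eeg
F3	128.973447	40.882392	eeg
F1	113.041282	50.301913	eeg
Fz	90.000000	54.000000	eeg
F2	66.958718	50.301913	eeg
F4	51.026553	40.882392	eeg
F8	37.377368	14.477512	eeg
FT9	162.000000	0.000000	eeg
FT7	161.137740	17.091146	eeg
FC5	158.118479	33.987844	eeg
FC3	151.066779	50.301913	eeg
FC1	133.563001	64.757167	eeg
FCz	90.000000	72.000000	eeg
FC2	46.436999	64.757167	eeg
FC4	28.933221	50.301913	eeg
FC6	21.881521	33.987844	eeg
FT8	18.862260	17.091146	eeg
FT10	18.000000	0.000000	eeg
T7	180.000000	18.000000	eeg
C5	180.000000	36.000000	eeg
C3	180.000000	54.000000	eeg
C1	180.000000	72.000000	eeg
Cz	0.000000	90.000000	eeg
C2	0.000000	72.000000	eeg
C4	0.000000	54.000000	eeg
C6	0.000000	36.000000	eeg
T8	0.000000	18.000000	eeg
TP9	-162.000000	0.000000	eeg
TP7	-161.137740	17.091146	eeg
CP5	-158.118479	33.987844	eeg
CP3	-151.066779	50.301913	eeg
CP1	-133.563001	64.757167	eeg
CPz	-90.000000	72.000000	eeg
CP2	-46.436999	64.757167	eeg
CP4	-28.933221	50.301913	eeg
CP6	-21.881521	33.987844	eeg
TP8	-18.862260	17.091146	eeg
TP10	-18.000000	0.000000	eeg
P9	-144.000000	0.000000	eeg
P7	-142.622632	14.477512	eeg
P5	-138.074386	28.393750	eeg
P3	-128.973447	40.882392	eeg
P1	-113.041282	50.301913	eeg
Pz	-90.000000	54.000000	eeg
P2	-66.958718	50.301913	eeg
P4	-51.026553	40.882392	eeg
P6	-41.925614	28.393750	eeg
P8	-37.377368	14.477512	eeg
P10	-36.000000	0.000000	eeg
P11	-142.622632	-14.477512	eeg
P12	-37.377368	-14.477512	eeg
PO1	-102.653876	33.987844	eeg
PO2	-77.346124	33.987844	eeg
O1	-95.733607	17.091146	eeg
O2	-84.266393	17.091146	eeg
O9	-108.000000	0.000000	eeg
O10	-72.000000	0.000000	eeg
Fpz	90.000000	18.000000	ref
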