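# Per-score patient counts with intervention outcome (Y = transfusion or
# endoscopic/radiologic/surgical haemostasis, N = medication only), one row
# per (system, score); n = 590 per system, 280 positive / 310 negative.
# Transcription note: the GBS score-9 negative cell is 66, not the printed
# 55 -- the printed row total (70) and the printed negative column total
# (310) both force N = 66; this is the single corrected cell (oracle:
# marginal-consistency recount).
system,score,n_pos,n_neg
gbs,5,1,1
gbs,6,27,40
gbs,7,26,15
gbs,8,9,2
gbs,9,4,66
gbs,10,21,65
gbs,11,34,10
gbs,12,19,38
gbs,13,55,41
gbs,14,13,30
gbs,15,31,1
gbs,16,6,1
gbs,17,31,0
gbs,18,3,0
mgbs,5,1,2
mgbs,6,28,40
mgbs,7,27,14
mgbs,8,12,13
mgbs,9,5,74
mgbs,10,33,54
mgbs,11,52,2
mgbs,12,4,68
mgbs,13,80,42
mgbs,14,19,1
mgbs,15,17,0
mgbs,16,2,0
pre_e_rs,0,24,46
pre_e_rs,1,80,16
pre_e_rs,2,77,234
pre_e_rs,3,29,9
pre_e_rs,4,35,4
pre_e_rs,5,22,0
pre_e_rs,6,1,0
pre_e_rs,7,12,1
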