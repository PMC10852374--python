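condition,subscale,raw_score,rasch_score
cts,tasks,6,0
cts,tasks,7,9
cts,tasks,8,16
cts,tasks,9,21
cts,tasks,10,26
cts,tasks,11,30
cts,tasks,12,34
cts,tasks,13,37
cts,tasks,14,41
cts,tasks,15,44
cts,tasks,16,47
cts,tasks,17,50
cts,tasks,18,53
cts,tasks,19,56
cts,tasks,20,59
cts,tasks,21,62
cts,tasks,22,65
cts,tasks,23,68
cts,tasks,24,72
cts,tasks,25,75
cts,tasks,26,79
cts,tasks,27,83
cts,tasks,28,88
cts,tasks,29,93
cts,tasks,30,100
dupuytren,tasks,6,0
dupuytren,tasks,7,19
dupuytren,tasks,8,30
dupuytren,tasks,9,37
dupuytren,tasks,10,43
dupuytren,tasks,11,49
dupuytren,tasks,12,53
dupuytren,tasks,13,57
dupuytren,tasks,14,61
dupuytren,tasks,15,65
dupuytren,tasks,16,69
dupuytren,tasks,17,72
dupuytren,tasks,18,76
dupuytren,tasks,19,80
dupuytren,tasks,20,84
dupuytren,tasks,21,89
dupuytren,tasks,22,93
dupuytren,tasks,23,97
dupuytren,tasks,24,100
cts,symptoms,3,0
cts,symptoms,4,15
cts,symptoms,5,27
cts,symptoms,6,38
cts,symptoms,7,48
cts,symptoms,8,59
cts,symptoms,9,71
cts,symptoms,10,85
cts,symptoms,11,100
dupuytren,symptoms,3,0
dupuytren,symptoms,4,27
dupuytren,symptoms,5,43
dupuytren,symptoms,6,54
dupuytren,symptoms,7,63
dupuytren,symptoms,8,71
dupuytren,symptoms,9,79
dupuytren,symptoms,10,88
dupuytren,symptoms,11,95
dupuytren,symptoms,12,100
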