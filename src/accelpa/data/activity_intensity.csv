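activity,intensity
lying_down,SB
reading,SB
computer_use,SB
standing,LPA
laundry,LPA
sweeping,LPA
biceps_curls,LPA
walking_slow,LPA
walking_fast,MVPA
jogging,MVPA
cycling,MVPA
stairs,MVPA
squats,MVPA
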