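video_id,second_index,probability
vid_a,0,0.9
vid_a,1,0.9
vid_a,2,0.9
vid_a,3,0.1
vid_a,4,0.6
vid_a,5,0.55
vid_a,6,0.2
vid_a,7,0.2
vid_a,8,0.2
vid_a,9,0.2
vid_a,10,0.5
vid_a,11,0.4
vid_b,0,0.05
vid_b,1,0.05
vid_b,2,0.05
vid_b,3,0.05
vid_b,4,0.05
vid_b,5,0.05
vid_b,6,0.05
vid_b,7,0.05
vid_b,8,0.05
vid_b,9,0.05
vid_b,10,0.05
vid_b,11,0.05
vid_c,0,0.7
vid_c,1,0.7
vid_c,2,0.7
vid_c,3,0.7
vid_c,4,0.7
vid_c,5,0.7
vid_c,6,0.7
vid_c,7,0.7
vid_c,8,0.7
vid_c,9,0.7
vid_c,10,0.7
vid_c,11,0.7
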