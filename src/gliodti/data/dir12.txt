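# 12 diffusion-encoding unit directions (electrostatic-repulsion set)
# columns: gx gy gz
-0.8071865960 -0.5881429143 0.0503757050
-0.9575454677 0.2286357972 0.1755914280
0.1069169476 -0.9729109391 0.2049709027
-0.5455387514 0.7813297021 0.3031688761
0.2845977008 0.8764079651 0.3884755172
0.8907302550 0.0785142804 0.4476998108
0.6293130629 -0.5867737995 0.5095699922
-0.3623157576 -0.7140771755 0.5990167603
-0.6797729669 -0.1054359599 0.7258043619
0.4214977492 0.3373492387 0.8417452932
-0.2677651664 0.4472578310 0.8533828263
0.1067248094 -0.2985080975 0.9484211779
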