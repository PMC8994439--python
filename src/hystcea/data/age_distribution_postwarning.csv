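age_bin,count
18-34,10137
35-44,39971
45-54,39145
55-64,8683
65+,7762
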