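{
 "comment": "logistic integrity classifier; training accuracy 0.875",
 "w": [
  -2.013515,
  -1.910738,
  3.375884
 ],
 "b": 0.274587,
 "mu": [
  2.838992,
  2.777757,
  1.934023
 ],
 "sd": [
  2.288221,
  2.179728,
  0.987683
 ]
}
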