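49a61f60104b2033d2a929427c7e374d0c652d2b87dfdbe5e19a356d516db221
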