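>(S9Y)15
SSSSSSSSSYSSSSSSSSSYSSSSSSSSSYSSSSSSSSSYSSSSSSSSSYSSSSSSSSSY
SSSSSSSSSYSSSSSSSSSYSSSSSSSSSYSSSSSSSSSYSSSSSSSSSYSSSSSSSSSY
SSSSSSSSSYSSSSSSSSSYSSSSSSSSSY
>(S4Y)30
SSSSYSSSSYSSSSYSSSSYSSSSYSSSSYSSSSYSSSSYSSSSYSSSSYSSSSYSSSSY
SSSSYSSSSYSSSSYSSSSYSSSSYSSSSYSSSSYSSSSYSSSSYSSSSYSSSSYSSSSY
SSSSYSSSSYSSSSYSSSSYSSSSYSSSSY
>(SSY)50
SSYSSYSSYSSYSSYSSYSSYSSYSSYSSYSSYSSYSSYSSYSSYSSYSSYSSYSSYSSY
SSYSSYSSYSSYSSYSSYSSYSSYSSYSSYSSYSSYSSYSSYSSYSSYSSYSSYSSYSSY
SSYSSYSSYSSYSSYSSYSSYSSYSSYSSY
>(YS)75
YSYSYSYSYSYSYSYSYSYSYSYSYSYSYSYSYSYSYSYSYSYSYSYSYSYSYSYSYSYS
YSYSYSYSYSYSYSYSYSYSYSYSYSYSYSYSYSYSYSYSYSYSYSYSYSYSYSYSYSYS
YSYSYSYSYSYSYSYSYSYSYSYSYSYSYS
>(YYS)50
YYSYYSYYSYYSYYSYYSYYSYYSYYSYYSYYSYYSYYSYYSYYSYYSYYSYYSYYSYYS
YYSYYSYYSYYSYYSYYSYYSYYSYYSYYSYYSYYSYYSYYSYYSYYSYYSYYSYYSYYS
YYSYYSYYSYYSYYSYYSYYSYYSYYSYYS
>Y150
YYYYYYYYYYYYYYYYYYYYYYYYYYYYYYYYYYYYYYYYYYYYYYYYYYYYYYYYYYYY
YYYYYYYYYYYYYYYYYYYYYYYYYYYYYYYYYYYYYYYYYYYYYYYYYYYYYYYYYYYY
YYYYYYYYYYYYYYYYYYYYYYYYYYYYYY
>S150
SSSSSSSSSSSSSSSSSSSSSSSSSSSSSSSSSSSSSSSSSSSSSSSSSSSSSSSSSSSS
SSSSSSSSSSSSSSSSSSSSSSSSSSSSSSSSSSSSSSSSSSSSSSSSSSSSSSSSSSSS
SSSSSSSSSSSSSSSSSSSSSSSSSSSSSS
>(S12Y3)10
SSSSSSSSSSSSYYYSSSSSSSSSSSSYYYSSSSSSSSSSSSYYYSSSSSSSSSSSSYYY
SSSSSSSSSSSSYYYSSSSSSSSSSSSYYYSSSSSSSSSSSSYYYSSSSSSSSSSSSYYY
SSSSSSSSSSSSYYYSSSSSSSSSSSSYYY
>(S24Y6)5
SSSSSSSSSSSSSSSSSSSSSSSSYYYYYYSSSSSSSSSSSSSSSSSSSSSSSSYYYYYY
SSSSSSSSSSSSSSSSSSSSSSSSYYYYYYSSSSSSSSSSSSSSSSSSSSSSSSYYYYYY
SSSSSSSSSSSSSSSSSSSSSSSSYYYYYY
>S120Y30
SSSSSSSSSSSSSSSSSSSSSSSSSSSSSSSSSSSSSSSSSSSSSSSSSSSSSSSSSSSS
SSSSSSSSSSSSSSSSSSSSSSSSSSSSSSSSSSSSSSSSSSSSSSSSSSSSSSSSSSSS
YYYYYYYYYYYYYYYYYYYYYYYYYYYYYY
>(S120Y30)scr
SSSSSSSSSSSSYSSYSYYYYSSSSSSSSSYSSSSSSSSYSSSSYSSSSSSSSYSSSSSS
SSSSSSYSSYYYSSSSSSYSYSYSSSSSSSYSSSYSSYSSSSSSSYSSSYYSSSSSYYSY
SYSYSSSSSSSSSYSSSSSSSSSSSYSSSS
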