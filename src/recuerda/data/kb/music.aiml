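<?xml version="1.0" encoding="utf-8"?>
<aiml version="subset-1.0">
  <topic name="music" description="música preferida por el paciente">
    <category role="trigger">
      <pattern>MÚSICA</pattern>
      <template><random>
        <li>¡La música alegra el corazón! ¿Es cierto que tu música preferida es <get name="musica_favorita"/>?</li>
        <li>¿Qué música te gusta escuchar para alegrarte?</li>
      </random></template>
    </category>
    <category role="trigger">
      <pattern>_ MÚSICA</pattern>
      <template><srai>MÚSICA</srai></template>
    </category>
    <category role="trigger">
      <pattern>MÚSICA _</pattern>
      <template><srai>MÚSICA</srai></template>
    </category>
    <category role="trigger">
      <pattern>_ MÚSICA _</pattern>
      <template><srai>MÚSICA</srai></template>
    </category>
    <category role="trigger">
      <pattern>CANCIONES</pattern>
      <template><srai>MÚSICA</srai></template>
    </category>
    <category role="trigger">
      <pattern>_ CANCIONES</pattern>
      <template><srai>MÚSICA</srai></template>
    </category>
    <category role="trigger">
      <pattern>CANCIONES _</pattern>
      <template><srai>MÚSICA</srai></template>
    </category>
    <category role="trigger">
      <pattern>_ CANCIONES _</pattern>
      <template><srai>MÚSICA</srai></template>
    </category>
    <category role="trigger">
      <pattern>CANCIÓN</pattern>
      <template><srai>MÚSICA</srai></template>
    </category>
    <category role="trigger">
      <pattern>_ CANCIÓN</pattern>
      <template><srai>MÚSICA</srai></template>
    </category>
    <category role="trigger">
      <pattern>CANCIÓN _</pattern>
      <template><srai>MÚSICA</srai></template>
    </category>
    <category role="trigger">
      <pattern>_ CANCIÓN _</pattern>
      <template><srai>MÚSICA</srai></template>
    </category>
    <category>
      <pattern>SÍ</pattern>
      <template><random>
        <li>¡Qué buen gusto! ¿Dónde escuchabas <get name="musica_favorita"/>?</li>
        <li>¿Qué recuerdos te trae <get name="musica_favorita"/>?</li>
      </random></template>
    </category>
    <category>
      <pattern>SI</pattern>
      <template><srai>SÍ</srai></template>
    </category>
    <category>
      <pattern>SÍ _</pattern>
      <template><srai>SÍ</srai></template>
    </category>
    <category>
      <pattern>SI _</pattern>
      <template><srai>SÍ</srai></template>
    </category>
    <category>
      <pattern>NO</pattern>
      <template>Entiendo. ¿Qué canciones te gustan más?</template>
    </category>
    <category role="fallback">
      <pattern>*</pattern>
      <template><random>
        <li>La música guarda memorias muy bonitas. ¿Me cuentas de tus canciones?</li>
        <li>Una buena melodía lo cura todo. ¿Cuál te hace sonreír?</li>
      </random></template>
    </category>
  </topic>
</aiml>
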